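"""Tissue-factor-pathway reaction network.

The network is the Hockin/Mann mass-action description of the extrinsic
coagulation pathway: tissue factor (TF) exposed to plasma binds fVII/fVIIa
to form the extrinsic tenase (TF:VIIa), which activates fX and fIX; fIXa
and thrombin-activated fVIIIa form the intrinsic tenase (IXa:VIIIa), the
dominant fXa producer of the propagation phase; fXa with thrombin-activated
fVa forms prothrombinase (Xa:Va), which converts prothrombin (II) to
thrombin (IIa) via meizothrombin (mIIa). TFPI shuts down the extrinsic
tenase trigger by trapping fXa; antithrombin (AT) irreversibly consumes
thrombin, meizothrombin, fIXa, fXa and (optionally) TF:VIIa.

Every reaction is elementary mass action with at most two reactants. The
rate constants live in ``data/rate_constants.yaml`` so the transcription
is auditable; :func:`load_rate_constants` validates completeness and
positivity against the reaction list.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import yaml

SPECIES: tuple[str, ...] = (
    "TF", "VII", "TF:VII", "VIIa", "TF:VIIa",
    "Xa", "IIa", "X", "TF:VIIa:X", "TF:VIIa:Xa",
    "IX", "TF:VIIa:IX", "IXa", "II", "VIII",
    "VIIIa", "IXa:VIIIa", "IXa:VIIIa:X", "VIIIa1-L", "VIIIa2",
    "V", "Va", "Xa:Va", "Xa:Va:II", "mIIa",
    "TFPI", "Xa:TFPI", "TF:VIIa:Xa:TFPI", "AT", "Xa:AT",
    "mIIa:AT", "IXa:AT", "IIa:AT", "TF:VIIa:AT",
)

SPECIES_INDEX: dict[str, int] = {s: i for i, s in enumerate(SPECIES)}

# (reactants, products, rate-constant key); reactants/products are species
# name tuples, repeated names meaning stoichiometry > 1 (never needed here).
REACTIONS: tuple[tuple[tuple[str, ...], tuple[str, ...], str], ...] = (
    (("TF", "VII"), ("TF:VII",), "k2"),
    (("TF:VII",), ("TF", "VII"), "k1"),
    (("TF", "VIIa"), ("TF:VIIa",), "k4"),
    (("TF:VIIa",), ("TF", "VIIa"), "k3"),
    (("TF:VIIa", "VII"), ("TF:VIIa", "VIIa"), "k5"),
    (("Xa", "VII"), ("Xa", "VIIa"), "k6"),
    (("IIa", "VII"), ("IIa", "VIIa"), "k7"),
    (("TF:VIIa", "X"), ("TF:VIIa:X",), "k8"),
    (("TF:VIIa:X",), ("TF:VIIa", "X"), "k9"),
    (("TF:VIIa:X",), ("TF:VIIa:Xa",), "k10"),
    (("TF:VIIa", "Xa"), ("TF:VIIa:Xa",), "k11"),
    (("TF:VIIa:Xa",), ("TF:VIIa", "Xa"), "k12"),
    (("TF:VIIa", "IX"), ("TF:VIIa:IX",), "k13"),
    (("TF:VIIa:IX",), ("TF:VIIa", "IX"), "k14"),
    (("TF:VIIa:IX",), ("TF:VIIa", "IXa"), "k15"),
    (("Xa", "II"), ("Xa", "IIa"), "k16"),
    (("IIa", "VIII"), ("IIa", "VIIIa"), "k17"),
    (("VIIIa", "IXa"), ("IXa:VIIIa",), "k18"),
    (("IXa:VIIIa",), ("VIIIa", "IXa"), "k19"),
    (("IXa:VIIIa", "X"), ("IXa:VIIIa:X",), "k20"),
    (("IXa:VIIIa:X",), ("IXa:VIIIa", "X"), "k21"),
    (("IXa:VIIIa:X",), ("IXa:VIIIa", "Xa"), "k22"),
    (("VIIIa",), ("VIIIa1-L", "VIIIa2"), "k23"),
    (("VIIIa1-L", "VIIIa2"), ("VIIIa",), "k24"),
    (("IXa:VIIIa:X",), ("VIIIa1-L", "VIIIa2", "X", "IXa"), "k25"),
    (("IXa:VIIIa",), ("VIIIa1-L", "VIIIa2", "IXa"), "k25"),
    (("IIa", "V"), ("IIa", "Va"), "k26"),
    (("Xa", "Va"), ("Xa:Va",), "k27"),
    (("Xa:Va",), ("Xa", "Va"), "k28"),
    (("Xa:Va", "II"), ("Xa:Va:II",), "k29"),
    (("Xa:Va:II",), ("Xa:Va", "II"), "k30"),
    (("Xa:Va:II",), ("Xa:Va", "mIIa"), "k31"),
    (("mIIa", "Xa:Va"), ("IIa", "Xa:Va"), "k32"),
    (("Xa", "TFPI"), ("Xa:TFPI",), "k33"),
    (("Xa:TFPI",), ("Xa", "TFPI"), "k34"),
    (("TF:VIIa:Xa", "TFPI"), ("TF:VIIa:Xa:TFPI",), "k35"),
    (("TF:VIIa:Xa:TFPI",), ("TF:VIIa:Xa", "TFPI"), "k36"),
    (("TF:VIIa", "Xa:TFPI"), ("TF:VIIa:Xa:TFPI",), "k37"),
    (("Xa", "AT"), ("Xa:AT",), "k38"),
    (("mIIa", "AT"), ("mIIa:AT",), "k39"),
    (("IXa", "AT"), ("IXa:AT",), "k40"),
    (("IIa", "AT"), ("IIa:AT",), "k41"),
    (("TF:VIIa", "AT"), ("TF:VIIa:AT",), "k42"),
)

# Conserved moieties: weight of each species in the protein's material
# balance. VIIIa2 (the dissociated A2 domain) carries weight 0 in the
# fVIII balance so that subunit loss conserves the VIIIa1-L-tracked moiety.
MOIETIES: dict[str, dict[str, float]] = {
    "TF": {s: 1.0 for s in SPECIES if s == "TF" or s.startswith("TF:")},
    "VII": {
        "VII": 1.0, "TF:VII": 1.0, "VIIa": 1.0, "TF:VIIa": 1.0,
        "TF:VIIa:X": 1.0, "TF:VIIa:Xa": 1.0, "TF:VIIa:IX": 1.0,
        "TF:VIIa:Xa:TFPI": 1.0, "TF:VIIa:AT": 1.0,
    },
    "X": {
        "X": 1.0, "TF:VIIa:X": 1.0, "IXa:VIIIa:X": 1.0, "Xa": 1.0,
        "TF:VIIa:Xa": 1.0, "Xa:Va": 1.0, "Xa:Va:II": 1.0, "Xa:TFPI": 1.0,
        "TF:VIIa:Xa:TFPI": 1.0, "Xa:AT": 1.0,
    },
    "IX": {
        "IX": 1.0, "TF:VIIa:IX": 1.0, "IXa": 1.0, "IXa:VIIIa": 1.0,
        "IXa:VIIIa:X": 1.0, "IXa:AT": 1.0,
    },
    "II": {
        "II": 1.0, "Xa:Va:II": 1.0, "mIIa": 1.0, "IIa": 1.0,
        "mIIa:AT": 1.0, "IIa:AT": 1.0,
    },
    "V": {"V": 1.0, "Va": 1.0, "Xa:Va": 1.0, "Xa:Va:II": 1.0},
    "VIII": {
        "VIII": 1.0, "VIIIa": 1.0, "IXa:VIIIa": 1.0, "IXa:VIIIa:X": 1.0,
        "VIIIa1-L": 1.0, "VIIIa2": 0.0,
    },
    "TFPI": {"TFPI": 1.0, "Xa:TFPI": 1.0, "TF:VIIa:Xa:TFPI": 1.0},
    "AT": {
        "AT": 1.0, "Xa:AT": 1.0, "mIIa:AT": 1.0, "IXa:AT": 1.0,
        "IIa:AT": 1.0, "TF:VIIa:AT": 1.0,
    },
}


class RateConstantError(ValueError):
    """Missing or non-positive rate constant."""


def load_rate_constants(path: str | None = None) -> dict[str, float]:
    """Load and validate the named mass-action constants.

    Validates that every reaction's rate-constant key is present and
    strictly positive. ``path=None`` loads the packaged defaults.
    """
    if path is None:
        text = (resources.files("coagxa.data") / "rate_constants.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    constants: dict[str, float] = {}
    for key, entry in raw.items():
        value = float(entry["value"] if isinstance(entry, dict) else entry)
        if not value > 0:
            raise RateConstantError(f"rate constant {key} must be > 0, got {value}")
        constants[key] = value
    needed = {k for _, _, k in REACTIONS}
    missing = needed - set(constants)
    if missing:
        raise RateConstantError(f"missing rate constant(s): {sorted(missing)}")
    return constants


@dataclass(frozen=True)
class ReactionNetwork:
    """Compiled network: species order, reaction arrows and index arrays.

    ``reactant_idx`` has one row per reaction with two entries (second
    entry -1 for unimolecular reactions); ``stoich`` is the net
    stoichiometry matrix (species x reactions); ``rates`` is the rate
    constant per reaction in reaction order.
    """

    species: tuple[str, ...]
    reactions: tuple[tuple[tuple[str, ...], tuple[str, ...], str], ...]
    rates: np.ndarray
    reactant_idx: np.ndarray
    stoich: np.ndarray

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_reactions(self) -> int:
        return len(self.reactions)


def build_network(
    constants: Mapping[str, float] | None = None,
    *,
    include_tf_viia_at: bool = True,
) -> ReactionNetwork:
    """Assemble the compiled network with the given rate constants.

    ``include_tf_viia_at`` toggles the direct AT inhibition of the
    TF:VIIa complex (present in the source kinetic model).
    """
    if constants is None:
        constants = load_rate_constants()
    reactions = tuple(
        r for r in REACTIONS
        if include_tf_viia_at or r[2] != "k42"
    )
    n_s, n_r = len(SPECIES), len(reactions)
    rates = np.empty(n_r)
    reactant_idx = np.full((n_r, 2), -1, dtype=np.int64)
    stoich = np.zeros((n_s, n_r))
    for j, (reactants, products, key) in enumerate(reactions):
        if key not in constants:
            raise RateConstantError(f"missing rate constant {key}")
        rates[j] = constants[key]
        if len(reactants) > 2:
            raise ValueError("only uni/bimolecular reactions supported")
        for pos, name in enumerate(reactants):
            reactant_idx[j, pos] = SPECIES_INDEX[name]
            stoich[SPECIES_INDEX[name], j] -= 1.0
        for name in products:
            stoich[SPECIES_INDEX[name], j] += 1.0
    return ReactionNetwork(
        species=SPECIES,
        reactions=reactions,
        rates=rates,
        reactant_idx=reactant_idx,
        stoich=stoich,
    )


def moiety_matrix(species: Sequence[str] = SPECIES) -> tuple[tuple[str, ...], np.ndarray]:
    """Return (moiety names, weight matrix) with one row per moiety."""
    names = tuple(MOIETIES)
    mat = np.zeros((len(names), len(species)))
    for i, m in enumerate(names):
        for s, w in MOIETIES[m].items():
            mat[i, list(species).index(s)] = w
    return names, mat
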