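# Mass-action rate constants for the tissue-factor-pathway coagulation model
# (Hockin/Mann extrinsic-pathway network). Each key is referenced by one or
# more reaction arrows in coagxa.network.REACTIONS.
#
# Units: second-order (association / substrate binding / fluid-phase
# activation) constants are M^-1 s^-1; first-order (dissociation, catalytic,
# cofactor decay) constants are s^-1.
k1:  {value: 3.1e-3, units: "1/s",    note: "TF:VII -> TF + VII"}
k2:  {value: 3.2e6,  units: "1/(M*s)", note: "TF + VII -> TF:VII"}
k3:  {value: 3.1e-3, units: "1/s",    note: "TF:VIIa -> TF + VIIa"}
k4:  {value: 2.3e7,  units: "1/(M*s)", note: "TF + VIIa -> TF:VIIa"}
k5:  {value: 4.4e5,  units: "1/(M*s)", note: "TF:VIIa + VII -> TF:VIIa + VIIa"}
k6:  {value: 1.3e7,  units: "1/(M*s)", note: "Xa + VII -> Xa + VIIa"}
k7:  {value: 2.3e4,  units: "1/(M*s)", note: "IIa + VII -> IIa + VIIa"}
k8:  {value: 2.5e7,  units: "1/(M*s)", note: "TF:VIIa + X -> TF:VIIa:X"}
k9:  {value: 1.05,   units: "1/s",    note: "TF:VIIa:X -> TF:VIIa + X"}
k10: {value: 6.0,    units: "1/s",    note: "TF:VIIa:X -> TF:VIIa:Xa (catalysis)"}
k11: {value: 2.2e7,  units: "1/(M*s)", note: "TF:VIIa + Xa -> TF:VIIa:Xa"}
k12: {value: 19.0,   units: "1/s",    note: "TF:VIIa:Xa -> TF:VIIa + Xa"}
k13: {value: 1.0e7,  units: "1/(M*s)", note: "TF:VIIa + IX -> TF:VIIa:IX"}
k14: {value: 2.4,    units: "1/s",    note: "TF:VIIa:IX -> TF:VIIa + IX"}
k15: {value: 1.8,    units: "1/s",    note: "TF:VIIa:IX -> TF:VIIa + IXa (catalysis)"}
k16: {value: 7.5e3,  units: "1/(M*s)", note: "Xa + II -> Xa + IIa"}
k17: {value: 2.0e7,  units: "1/(M*s)", note: "IIa + VIII -> IIa + VIIIa"}
k18: {value: 1.0e7,  units: "1/(M*s)", note: "VIIIa + IXa -> IXa:VIIIa"}
k19: {value: 5.0e-3, units: "1/s",    note: "IXa:VIIIa -> VIIIa + IXa"}
k20: {value: 1.0e8,  units: "1/(M*s)", note: "IXa:VIIIa + X -> IXa:VIIIa:X"}
k21: {value: 1.0e-3, units: "1/s",    note: "IXa:VIIIa:X -> IXa:VIIIa + X"}
k22: {value: 8.2,    units: "1/s",    note: "IXa:VIIIa:X -> IXa:VIIIa + Xa (catalysis)"}
k23: {value: 6.0e-3, units: "1/s",    note: "VIIIa -> VIIIa1-L + VIIIa2 (A2 subunit loss)"}
k24: {value: 2.2e4,  units: "1/(M*s)", note: "VIIIa1-L + VIIIa2 -> VIIIa"}
k25: {value: 1.0e-3, units: "1/s",    note: "intrinsic-tenase-bound VIIIa decay (two arrows)"}
k26: {value: 2.0e7,  units: "1/(M*s)", note: "IIa + V -> IIa + Va"}
k27: {value: 4.0e8,  units: "1/(M*s)", note: "Xa + Va -> Xa:Va"}
k28: {value: 0.2,    units: "1/s",    note: "Xa:Va -> Xa + Va"}
k29: {value: 1.0e8,  units: "1/(M*s)", note: "Xa:Va + II -> Xa:Va:II"}
k30: {value: 103.0,  units: "1/s",    note: "Xa:Va:II -> Xa:Va + II"}
k31: {value: 63.5,   units: "1/s",    note: "Xa:Va:II -> Xa:Va + mIIa (catalysis)"}
k32: {value: 1.5e7,  units: "1/(M*s)", note: "mIIa + Xa:Va -> IIa + Xa:Va"}
k33: {value: 9.0e5,  units: "1/(M*s)", note: "Xa + TFPI -> Xa:TFPI"}
k34: {value: 3.6e-4, units: "1/s",    note: "Xa:TFPI -> Xa + TFPI"}
k35: {value: 3.2e8,  units: "1/(M*s)", note: "TF:VIIa:Xa + TFPI -> TF:VIIa:Xa:TFPI"}
k36: {value: 1.1e-4, units: "1/s",    note: "TF:VIIa:Xa:TFPI -> TF:VIIa:Xa + TFPI"}
k37: {value: 5.0e7,  units: "1/(M*s)", note: "TF:VIIa + Xa:TFPI -> TF:VIIa:Xa:TFPI"}
k38: {value: 1.5e3,  units: "1/(M*s)", note: "Xa + AT -> Xa:AT"}
k39: {value: 7.1e3,  units: "1/(M*s)", note: "mIIa + AT -> mIIa:AT"}
k40: {value: 4.9e2,  units: "1/(M*s)", note: "IXa + AT -> IXa:AT"}
k41: {value: 7.1e3,  units: "1/(M*s)", note: "IIa + AT -> IIa:AT"}
k42: {value: 2.3e2,  units: "1/(M*s)", note: "TF:VIIa + AT -> TF:VIIa:AT"}
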