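# Default synthetic-cohort specification emulating the printed plasma-factor
# distributions of the Leiden Thrombophilia Study population (per-factor
# percent-of-mean mean, SD and observed range, separately for healthy
# controls and first-DVT cases), plus demographic marginals.
#
# Factor levels are sampled as truncated normals on the printed ranges;
# correlations default to independence (a correlation matrix may be supplied).
group_sizes:
  control: 473
  case: 426
factors:
  control:
    fII:   {mean: 104, sd: 15, min: 63, max: 153}
    fV:    {mean: 131, sd: 33, min: 47, max: 302}
    fVII:  {mean: 110, sd: 22, min: 41, max: 171}
    fVIII: {mean: 122, sd: 33, min: 49, max: 232}
    fIX:   {mean: 103, sd: 21, min: 52, max: 188}
    fX:    {mean: 103, sd: 17, min: 49, max: 163}
    AT:    {mean: 99,  sd: 10, min: 63, max: 125}
    TFPI:  {mean: 92,  sd: 21, min: 46, max: 171}
  case:
    fII:   {mean: 108, sd: 17, min: 67, max: 178}
    fV:    {mean: 133, sd: 35, min: 41, max: 305}
    fVII:  {mean: 114, sd: 25, min: 53, max: 200}
    fVIII: {mean: 141, sd: 35, min: 53, max: 318}
    fIX:   {mean: 109, sd: 26, min: 63, max: 209}
    fX:    {mean: 107, sd: 20, min: 58, max: 174}
    AT:    {mean: 99,  sd: 11, min: 67, max: 143}
    TFPI:  {mean: 94,  sd: 21, min: 35, max: 159}
demographics:
  # fraction female per group (272/473 controls, 254/426 cases)
  p_female: {control: 0.575, case: 0.596}
  age: {mean: 45.0, sd: 13.0, min: 18.0, max: 71.0}
  bmi: {mean: 25.5, sd: 3.8, min: 16.0, max: 45.0}
  # probability of oral-contraceptive use among women younger than 50
  p_oc_given_young_female: {control: 0.34, case: 0.43}
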