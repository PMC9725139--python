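# tcsgain

Deterministic analysis of mono-/bistability in positively autoregulated
bacterial two-component signaling systems (TCS), in the presence of competing
transcription-factor binding sites (TFBSs), via modular logarithmic gains.

The closed feedback loop is opened into three modules acting on the total
transcription-factor level `R_T*` (all quantities normalized by the
autoregulated-promoter affinity `K_auto`):

1. **Activation** `A`: phosphorylation of the response regulator, parameterized
   by the phosphorylation capacity `Cp*` and the composite `Ct*` (plus a full
   mass-action bifunctional-kinase model to validate the approximation).
2. **Binding** `B`: sequestration of active TF by `D*` competing sites of
   relative affinity `K*`, yielding the free level `R_f*`.
3. **Transcription** `F`: Hill autoregulation with fold change `f` and
   cooperativity `h`, optionally coupled to a negative feedback.

The product of the three logarithmic gains, `LG_3 = LG_F * LG_B * LG_A`,
exceeds 1 only where bistability is possible (a necessary condition). The
package finds fixed points of the composed map with stability labels, traces
dose-response branches and saddle-node folds over `Cp*` sweeps, and draws
mono-/bistability phase diagrams with the `LG_3 = 1` contour.

A second group of tools scores binding-site strength: per-site information
content (bits) from aligned TFBS sets, median-subtracted log10 ChIP peak
intensities, TF/TFBS abundance-ratio summaries, and decoy-plasmid copy-number
arithmetic.

## Library example

```python
import numpy as np
from tcsgain import SystemParams, lg3_profile, steady_states

params = SystemParams(f=5, h=2, D_star=4, K_star=0.5, R_b_star=2.5,
                      Ct_star=3, Cp_star=50)
profile = lg3_profile(params, np.geomspace(0.1, 100, 200))
print(profile.max_LG_3)                 # > 1: bistability possible
for s in steady_states(params):
    print(s.R_T_star, s.stability)      # two stable, one unstable
```

## CLI

All analysis subcommands accept `--config params.yaml` (keys = `SystemParams`
field names, or dimensional `Cp`, `Ct`, `D`, `K`, `Rb` together with
`K_auto`), per-parameter override flags, and write a tidy TSV plus a JSON
metadata sidecar:

```sh
tcsgain lg-profile    --config params.yaml --out profile.tsv
tcsgain steady-states --config params.yaml --out states.tsv
tcsgain dose-response --config params.yaml --cp-min 1 --cp-max 300 --out dr.tsv
tcsgain phase-diagram --K_star 0.5 --axis1 f:1:100:40 --axis2 Cp_star:0.1:100:40 --out pd.tsv
tcsgain simulate-full --rho 20 --out curve.tsv
tcsgain site-info     --fasta sites.fasta --out ri.tsv
tcsgain chip-delta    --peaks peaks.tsv --out delta.tsv
tcsgain ratios        --table abundance.tsv --out ratios.tsv
tcsgain decoys        --relative-signal 0.62 --base-copy-number 96 --sites-per-plasmid 1
tcsgain fixtures      --kind pwm-sites --seed 1 --n 50 --out sites.fasta
```

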