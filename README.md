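# dpcrkit

Absolute quantification of genome-editing outcomes from droplet digital PCR
(dPCR), with detection-limit statistics and an ODE model of nuclease
cleavage and DNA repair kinetics.

## The problem

When a programmable nuclease (Cas9, Cas12, TALEN, …) cuts a locus, the
outcome is not just "edited or not": loci end up as wildtype, small indels,
large deletions, unresolved double-strand breaks (DSBs), targeted
integrations of a donor template, chromosome-arm losses, or other
aberrations — and a large share of cuts are repaired *precisely*, leaving
no sequence scar at all. Sequencing-based readouts miss several of these
classes and cannot see precise repair. Two-colour dPCR can: each droplet
well partitions ~2×10⁴ reactions, and Poisson statistics on the negative
droplet fraction give absolute molecule counts per channel,

λ = ln(n_total / n_negative),  copies = λ·n_total,

while the excess of double-positive droplets over chance measures whether
two probed sequences still sit on one physical molecule (linkage) — the
signature of an intact, un-broken locus.

`dpcrkit` implements, for users designing or analysing such panels:

* **dpcr_core** — Poisson inversion, linkage decomposition, bootstrap CIs;
* **assays** — edge / flanking / aneuploidy / targeted-integration assay
  logic and the *double normalisation* (assay ÷ reference, then ÷ the same
  ratio in an unedited mock) that turns copy counts into absolute outcome
  fractions;
* **detection_limits** — LoB = μ_blank + 1.645·σ_blank,
  LoD = LoB + 1.645·σ_low, plus dilution-series linearity;
* **kinetics** — the three-state model
  `WT →(k_dsb·D(t)) DSB →(k_pr) WT, →(k_in) indel, →(k_ld) large del,
  →(k_ti) TI` with trafficking delay D(t)=1−e^(−t/τ), fitted jointly to
  ±repair-inhibitor conditions (shared k_dsb, τ; per-condition repair
  rates) with bootstrap CIs, plus derived statistics (half-lives ln2/k,
  hourly repair likelihoods, cleavage events per product K/k_x, recurrent
  cleavage cohorts);
* **synthetic** — molecule-level droplet simulation and noisy timeseries
  with declared ground truth, so the whole stack is testable without
  instrument data.

See `docs/methods.md` for model details and numerical choices.

## Worked example

Quantify a simulated edited sample against its mock, then fit kinetics:

```python
from dpcrkit import (AssayPanelConfig, LocusGroundTruth, quantify,
                     simulate_panel_wells, fit_kinetics, simulate_timeseries,
                     derive_kinetics)
from dpcrkit.assays import AssayEntry
from dpcrkit.kinetics import RateCoefficients, RepairRates

panel = AssayPanelConfig(
    locus="locusA",
    assays=[
        AssayEntry("edge1", "edge", {"fam": "cleavage", "hex": "distal"}),
        AssayEntry("flank1", "flanking", {"fam": "flank5", "hex": "flank3"},
                   distance_bp=120),
        AssayEntry("ref1", "reference", {"fam": "ref"}),
    ],
)
truth = LocusGroundTruth(wt=0.15, indel=0.40, large_del_5=0.10,
                         dsb=0.25, other_loss=0.10)
wells = simulate_panel_wells(truth, panel, "edited", seed=11)
s = quantify(wells, panel)[0]
print(f"wt {s.wt:.1f}±{s.sd['wt']:.1f}  indel {s.indel:.1f}±{s.sd['indel']:.1f}  "
      f"large_del {s.large_del:.1f}  dsb {s.dsb:.1f}  other {s.other_aberration:.1f}  "
      f"total {s.total:.1f}")

rates = RateCoefficients(
    k_dsb=0.63, tau=0.5,
    conditions={"untreated": RepairRates(k_pr=0.554, k_in=0.105, k_ld=0.065),
                "inhibited": RepairRates(k_pr=0.135, k_in=0.005, k_ld=0.025)})
series = simulate_timeseries(rates, [0.083, 0.5, 1, 2, 3, 4, 6, 8, 12, 16, 20, 24],
                             noise_sd=2.0, seed=7, states=("WT", "DSB", "IN", "LD"))
fit = fit_kinetics(series, n_boot=200, n_starts=10, seed=8)
der = derive_kinetics(fit.point.condition("untreated"))
print(f"k_dsb = {fit.point.k_dsb:.3f}/h  (95% CI {fit.ci['k_dsb'][0]:.3f}-{fit.ci['k_dsb'][1]:.3f})")
print(f"DSB resolution half-life = {der.half_life_resolution:.2f} h")
print("cleavage events per product: " +
      ", ".join(f"{k}={v:.1f}" for k, v in der.dsbs_per_product.items()))
```

prints

```
wt 14.9±0.6  indel 40.1±0.7  large_del 9.5  dsb 26.1  other 9.5  total 100.0
k_dsb = 0.601/h  (95% CI 0.564-0.642)
DSB resolution half-life = 1.02 h
cleavage events per product: pr=1.3, in=6.7, ld=10.1
```

The first line is the absolute stacked outcome summary (mean ± sd over the
three simulated technical replicate wells): every class is within sampling
noise of the generating mixture and the classes sum to 100% of genome
copies. The fit then recovers the cleavage rate from noisy two-condition
data (truth 0.63/h inside the bootstrap CI), converts the total repair rate
K into a ~1 h DSB half-life, and reports that on average ~1.3 cuts produce
one precise repair while an indel needs ~7 and a large deletion ~10 —
i.e. most cleavage events are repaired without a scar and loci are cut
repeatedly.

The same stages are scriptable from the shell:

```sh
dpcrkit simulate --scenario scenario.yaml --seed 3 --out-dir run/
dpcrkit quantify --droplets run/droplets.csv --panel panel.yaml --out summary.csv
dpcrkit lod      --input dilution.csv --out lod.json
dpcrkit fit      --timeseries run/timeseries.csv --seed 1 --out fit.json
```

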