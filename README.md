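# fkpkit

Analysis toolkit for the evolution and biochemistry of bifunctional
**L-fucokinase/GDP-fucose pyrophosphorylases (FKPs)** — single
polypeptides that fuse an N-terminal GDP-fucose pyrophosphorylase
(GFPP) domain to a C-terminal L-fucokinase (FUK) domain and catalyse
both steps of the fucose salvage pathway (L-Fuc + ATP → Fuc-1-P;
Fuc-1-P + GTP → GDP-Fuc + PPi). It is written for molecular
evolutionists and enzymologists who want to classify FKP-like domain
architectures, test whether the fused proteins descend from a single
ancestral fusion event, and quantify the enzymes' kinetics and thermal
stability — with every step exercisable on seeded synthetic data whose
ground truth is known.

## What it does

| Module | Purpose |
| --- | --- |
| `fkpkit.simulate` | Seeded generators: fused/monofunctional protein families, ranked profile-HMM hit tables, single-fusion-gain trees, initial-rate datasets, melt curves, a census alignment — each with truth labels |
| `fkpkit.domains` | Classify FUK / GFPP / bifunctional-FKP sets from ranked hmmscan-style hits (top-model rules + length filters 333/406/739–1745 aa) |
| `fkpkit.ssn` | All-by-all percent-identity sequence similarity networks, threshold clustering, cluster-vs-clade congruence |
| `fkpkit.phylo` | Midpoint rooting, monophyly tests, enumeration of monophyly-compatible root positions, minimal clade cover, fusion gain/loss parsimony (unordered and single-gain Dollo) |
| `fkpkit.conservation` | Reference-anchored residue conservation census (G75, R79, K88, R597, D606, D767) with the N-terminal exclusion rule and clade stratification |
| `fkpkit.kinetics` | Coupled-assay rate extraction, Michaelis–Menten and substrate-inhibition fits (v = kcat·E0·S/(KM + S + S²/Ki)), kcat/KM with quadrature error propagation, mutant normalization |
| `fkpkit.meltcurve` | Derivative-trough Tm extraction from biphasic thermal-shift curves, contaminant exclusion windows, paired ΔTm |
| `fkpkit.pipeline` / `fkpkit.cli` | End-to-end orchestration with YAML config, per-stage seeds and a checksummed run manifest |

The scientific core, in the field's notation: membership rules over
ranked profile-HMM hits (COG2605 = FUK, PF07959 = GFPP, PRK13412 =
full-length FKP); Fitch/Sankoff small parsimony for the binary fusion
character, with the single-gain hypothesis assessed by enumerating root
positions under which the fused tips are monophyletic; v =
k_cat·[E]₀·[S]/(K_M + [S]) and its uncompetitive substrate-inhibition
extension peaking at √(K_M·K_i); catalytic efficiency k_cat/K_M with
(σ_eff/eff)² = (σ_kcat/k_cat)² + (σ_KM/K_M)²; and T_m as the trough of
−dF/dT of dye fluorescence, with ΔT_m the mean of paired replicate
differences. Details and defaults: [docs/methods.md](docs/methods.md).

## Worked example

```python
import numpy as np
from fkpkit.simulate import (SimConfig, KineticTruth, MeltTruth,
                             gen_domain_families, gen_hit_table,
                             gen_rate_data, gen_melt_curve)
from fkpkit import domains
from fkpkit.kinetics import fit_mm
from fkpkit.meltcurve import analyze_curve

# 1. classify a synthetic 15-protein dataset from its hit table
proteins, truth = gen_domain_families(SimConfig(seed=42))
hits = gen_hit_table(proteins, truth, score_noise_sd=0.0)
calls = domains.classify_architecture(
    domains.rank_models(hits), {p: len(s) for p, s in proteins.items()})
print("FKP-set proteins:", sorted(calls.query_id[calls.in_fkp_set]))

# 2. fit noisy saturation data generated at the fucokinase parameters
kt = KineticTruth(KM=77.0, kcat=0.90, E0=0.277, noise_cv=0.05)
data = gen_rate_data(kt, 77.0 * np.array([0.25, 0.5, 1, 2, 3, 5, 8, 10]),
                     n_reps=3, seed=42)
fit = fit_mm(data, kt.E0)
eff, eff_sd = fit.efficiency
print(f"KM = {fit.KM:.0f} +/- {fit.KM_sd:.0f} uM, "
      f"kcat = {fit.kcat:.2f} +/- {fit.kcat_sd:.2f} /s")
print(f"kcat/KM = {eff:.3g} +/- {eff_sd:.2g} /M/s")

# 3. extract both melting temperatures from a noisy biphasic melt curve
mt = MeltTruth(transitions=((43.8, 1.0, 500.0), (52.5, 1.0, 700.0)),
               noise_sd=2.0)
res = analyze_curve(gen_melt_curve(mt, seed=42))
print(f"Tm1 = {res.tm1:.1f} C, Tm2 = {res.tm2:.1f} C")
```

Output:

```
FKP-set proteins: ['fkp_0001', 'fkp_0002', 'fkp_0003', 'fkp_0004', 'fkp_0005']
KM = 75 +/- 4 uM, kcat = 0.89 +/- 0.01 /s
kcat/KM = 1.19e+04 +/- 7.3e+02 /M/s
Tm1 = 43.8 C, Tm2 = 52.5 C
```

All five fused proteins (and only those) enter the FKP set; the fit
recovers the generating parameters KM = 77 µM and kcat = 0.90 s⁻¹
within their uncertainties; and the derivative troughs land on the two
synthesis midpoints to within the 0.5 °C temperature grid.

The same functionality is exposed as a CLI:

```bash
fkpkit pipeline --seed 3 --outdir demo_run     # full synthetic pipeline
fkpkit phylo events tree.nwk --states A=1,B=1,C=0,D=0
fkpkit kinetics efficiency --kcat 0.90 0.07 --km 77 19
```

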