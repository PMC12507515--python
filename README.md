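# cas12akin

Analysis pipeline for comparing CRISPR–Cas12a nucleases: cis-cleavage
kinetics from gel densitometry, trans-cleavage rates from reporter
fluorescence, thermal-shift melting temperatures, and REC2–Nuc domain
dynamics from coordinate trajectories.

## The problem

Cas12a cleaves double-stranded DNA sequentially: it first nicks the
non-target strand (NTS), relaxing a supercoiled plasmid to the open-circle
form, then cleaves the target strand (TS) to linearize it. Quantifying a
cleavage time course on a gel therefore yields three topology fractions —
supercoiled (SC), nicked, linear — whose interconversion encodes two rate
constants, `k_NTS` and `k_TS`. These rates differ by orders of magnitude
across orthologues and mutants, and comparing them requires a consistent
pipeline from raw band intensities to fitted rate constants.

This package implements that pipeline:

1. **Densitometry correction** (`cas12akin.densitometry`). Intercalating
   stains respond differently to each topology. A calibration dilution
   series of equal parts nicked/linear/supercoiled DNA gives per-topology
   response slopes `s_i` (least squares through the origin); correction
   factors `f_i = mean(s)/s_i` equalize corrected signal at equal mass.
   Corrected intensities are summed per lane and converted to percentages.
2. **Kinetic model** (`cas12akin.cis_kinetics`). A six-compartment linear
   ODE system

       SC  --ka-->  NICK  --kb-->  LIN
       SC  --kini--> ucSC,  NICK --kini2--> ucNICK,
       NICK1 --ka--> NICK,  NICK1 --kini--> ucNICK

   with observables `TotSC = SC + ucSC`, `TotNICK = NICK + NICK1 + ucNICK`,
   `LIN`. `ka = k_NTS`, `kb = k_TS`; `kini`/`kini2` absorb material that
   never completes a step; `NICK1` holds plasmid that is already nicked at
   t = 0. The system is solved exactly by the matrix exponential, and rates
   are fitted per replicate by bounded least squares (8 multistarts from
   the standard initial guesses ka = kb = 0.50, kini = kini2 = 0.01 s⁻¹),
   then aggregated to condition means ± s.d. with fold changes versus a
   reference ("3.9× faster" / "5.1× slower").
3. **Assay curves** (`cas12akin.assay_curves`). Pseudo-first-order trans
   rates as the OLS slope over the first 300 s of a fluorophore–quencher
   reporter curve; melting temperature as the fluorescence peak of a
   25–99 °C melt curve (explicit no-peak outcome for degenerate curves).
4. **Domain dynamics** (`cas12akin.domain_dynamics`). From multi-model PDB
   trajectories: per-frame mass-weighted centre-of-mass distance between
   the REC2 and Nuc domains (built-in residue ranges for FnCas12a,
   LbCas12a, AsCas12a), heavy-atom contact counts at a strict < 3.5 Å
   cutoff, residue pairs ranked by contact occupancy, and Gaussian-KDE
   summaries (Scott's rule) with mode and multimodality detection.
5. **Synthetic data** (`cas12akin.synthetic_data`). Seeded generators for
   every input above, each the exact forward model of its analysis stage,
   so the whole pipeline is testable end-to-end with known ground truth.

## Worked example

Fit rates from a synthetic two-condition experiment (3 replicates each,
2-percentage-point densitometry noise) and summarize:

```python
import numpy as np
from cas12akin import cis_kinetics as ck, synthetic_data as sd

truth = ck.CleavageParams(ka=0.2, kb=0.02, kini=0.005, kini2=0.01)
spec = sd.SynthSpec(seed=21, noise_sd=2.0, n_replicates=3,
                    time_grid=tuple([0.0] + list(np.geomspace(0.25, 300, 15))))
reps = sd.gen_timecourse(truth, ck.InitialState(100.0), spec)
fits = [ck.fit_replicate(tc, replicate=i) for i, tc in enumerate(reps)]
cond = ck.aggregate_condition(fits, condition="wt")
print(f"k_NTS = {cond.ka_mean:.3f} +/- {cond.ka_sd:.3f} /s")
print(f"k_TS  = {cond.kb_mean:.4f} +/- {cond.kb_sd:.4f} /s")
```

prints

```
k_NTS = 0.199 +/- 0.006 /s
k_TS  = 0.0198 +/- 0.0012 /s
```

i.e. the planted `k_NTS = 0.2 /s` and `k_TS = 0.02 /s` are recovered
within the replicate scatter. The same workflow runs from the shell:

```sh
cas12akin pipeline --outdir results/     # synth -> gel-correct -> fit-cis -> report
cas12akin melt-tm melt.csv --outdir results/
cas12akin domain-dist trajectory.pdb --outdir results/
```

Each stage writes CSV tables stamped with the config hash and seed, so
re-running with an unchanged config is byte-identical.

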