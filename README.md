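# blephagrip

Biomechanics of suction attachment in net-winged midge (Blephariceridae)
larvae — aquatic insects that cling to rock in torrential alpine streams with
six ventral suction organs, withstanding shear loads of hundreds to over a
thousand times their body weight.

The package is for comparative biomechanists and experimentalists who run
whole-animal centrifuge assays or surface profilometry and need a tested,
scriptable pipeline for:

* **centrifuge forces** — peak detachment force `F = m (2πf)² r` and force per
  body weight `(2πf)² r / g`, with the standard handling of censored trials
  (specimens that outlast the rig's 75 rps ceiling inherit the maximum
  detached conspecific acceleration) and peak-per-individual reduction;
* **suction stress** — force over contact area under bracketing assumptions:
  *conservative* (six organs, fringe-inclusive fitted circle) and *realistic*
  (`conservative / ((1 − fringe_fraction) · organs_in_contact / n_organs)`,
  default 33% fringe and 3 of 6 organs), per individual then mean ± SD;
* **microtrichia stiffness** — a lower bound on the elastic modulus of the
  disc's spine-like microtrichia from large-deflection (elastica) beam
  theory: a cylindrical cantilever at angle α to the substrate under a
  perpendicular tip load F stays clear of side contact only if

  `E ≥ F L² / ( I · [K(½) − F(φₐ | ½)]² )`, `φₐ = arcsin(sin((90°−α)/2)/p)`,
  `p² = ½`, `I = πD⁴/64`,

  with an independent shooting-method ODE oracle for validation;
* **surface metrology** — Ra / Rq / PV roughness of height maps and
  shape-from-focus reconstruction from focal Z-stacks;
* **group statistics** — Kruskal–Wallis + Dunn/Holm and log₁₀-ANOVA + Tukey
  pipelines with geometric-mean fold changes;
* **synthetic data** — generators for trials, rough surfaces and Z-stacks
  carrying the measured species profiles (e.g. 1120 ± 282 body weights for
  *Hapalothrix lugubris* on smooth substrate), so everything runs without
  downloads.

## Worked example

Divide the measured peak normal force of *H. lugubris* (11.6 mN) over six
organs and the ~34,300 microtrichia tips per disc, then bound the cuticle
stiffness over the observed 40–50° contact-angle range:

```python
from blephagrip import LoadSharing, MicrotrichiumBeam, realistic_stress, stiffness_scan

ls = LoadSharing()                       # 11.6 mN, 6 organs, 49,000 µm² @ 0.7 µm⁻²
print(f"tips per organ      : {ls.microtrichia_count:,.0f}")
print(f"load per tip        : {ls.per_tip_force*1e9:.1f} nN")
scan = stiffness_scan(MicrotrichiumBeam(tip_force=ls.per_tip_force), [40, 45, 50])
print(scan.to_string(index=False))
print(f"realistic shear     : {realistic_stress(39.3):.1f} kPa")
```

prints

```
tips per organ      : 34,300
load per tip        : 56.4 nN
 alpha_deg  E_crit_gpa
      40.0    0.369232
      45.0    0.326739
      50.0    0.292582
realistic shear     : 117.3 kPa
```

Each microtrichium carries ≈56 nN; keeping tip contact over the 40–50° range
requires a cuticle modulus of at least ≈0.3–0.4 GPa (the bound falls with
steeper contact angles, so the scan minimum is the operative bound — wood-like
stiffness, consistent with sclerotised cuticle). Correcting the 39.3 kPa
conservative shear stress for the fringe layer and 3-of-6 organ contact gives
117 kPa.

The full synthetic pipeline (simulate → censor → peaks → stress → statistics →
stiffness → roughness) runs from the shell:

```sh
blephagrip run --seed 1 --out demo/
# pipeline complete: 90 trials, 1 censored; report in demo/
```

`demo/report.json` then holds, e.g., the substrate comparison for the
simulated *H. lugubris* trials (Kruskal–Wallis H = 37.8, p ≈ 6e-9; smooth vs
micro-rough fold change ≈ 1.8, reproducing the measured ≈2-fold drop) and the
roughness of a simulated micro-rough surface (Ra = 0.32 µm by construction).
Individual stages are exposed as `blephagrip simulate | centrifuge | stress |
stiffness | roughness | sff | compare`.

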