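# pfa-fieldsim

Desk-scale biophysical comparison of pulsed-field-ablation (PFA) catheter
designs for pulmonary vein isolation, using waveform-independent
electro-quasistatic field simulation.

## The problem

Several PFA catheter families are in clinical use or trials — penta-spline
baskets, Nitinol mesh spheres (a focal 9 mm device and a large one-shot
sphere of diamond panels), circular decapolar loops, flexible-circuit spline
arrays, and electrode-bearing balloons. Their pulse waveforms are
proprietary, which seems to block head-to-head comparison. It does not:
at any instant during a pulse the potential obeys the static volume-conductor
equation

∇ · ( σ(|∇φ|) ∇φ ) = 0,

so the *fraction* of delivered power reaching an atrial-wall target, and the
current required to electroporate the full wall thickness, depend only on
electrode geometry, vectoring (the polarity assignment of each energy
delivery), and anatomy — not on pulse timing. This package implements that
comparison on a synthetic left-pulmonary-vein antrum phantom: a blood-filled
vein opening into a chamber, wrapped by a 2.5 mm myocardial shell, with a
6 × 47 mm circumferential target band and a distant grounded return patch
for monopolar designs.

Three outcome metrics are computed per design:

* **Current for 90% transmurality** — the smallest per-vector current (A)
  at which 90% of the target band's volume sees |E| > 600 V/cm, a
  conservative lethal-electroporation threshold for myocardium. Less
  current is safer.
* **Electrode current density (ECD)** — per-vector current divided by the
  sourcing electrode's metal area (A/cm²), a proxy for local heating and
  bubble generation.
* **Efficiency** — percent of delivered generator power (I·V) dissipated
  inside the target band, computed as ∫_target σ|∇φ|² dV / Σ I·V.

The solver is a finite-volume 7-point discretization on the voxel grid with
harmonic face-conductivity averaging, Dirichlet electrode potentials,
insulating outer boundaries, Picard iteration for field-dependent
conductivity σ(|E|), and exact (linear) or secant (nonlinear) current
control.

## Worked example

Compare the flexible-spline catheter with its balloon variant (identical
electrode layout; the balloon adds an insulating body filling the lumen
behind the electrodes) on the default antrum phantom at 1 mm voxels:

```
$ pfa-fieldsim run --designs flex_splines,balloon --spacing 1.0

      design  current_for_90_transmurality_a  transmurality_achieved  electrode_area_cm2  ecd_a_per_cm2  n_vectors_on_target  ecd_times_n  efficiency_percent  lesion_volume_mm3
flex_splines                             6.1                    True              0.1296             47                    8          378            6.882028             2124.0
     balloon                             2.0                    True              0.1296             15                    8          123           41.187576             1854.0
```

Reading: both designs place eight on-target vectors (four tripole vectors
per application, two rotated applications). The flexible splines need
6.1 A per vector to render 90% of the band transmural, and 6.9% of their
delivered power lands in the target; the rest shunts through the blood
pool. The balloon blocks that shunt path, so it reaches transmurality at
the 2 A search floor and concentrates 41% of its power in the target, with
correspondingly lower ECD (15 vs 47 A/cm²). The same run over all six
designs reproduces the published ordering: the exposed-electrode monopolar
spheres are least efficient and need the most current, the shielded/discrete
bipolar designs (circular, flex, balloon) the least.

Other entry points: `pfa-fieldsim validate` runs the closed-form solver
checks (uniform field, spreading resistance, power conservation);
`pfa-fieldsim tables` prints the dose-duration and ECD arithmetic from the
published schedule inputs; `pfa-fieldsim run --config run.yaml` takes a full
YAML configuration (phantom geometry, conductivity table, solver tolerances,
designs).

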