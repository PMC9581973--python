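# nucleodope

Analysis machinery for studying how single-stranded DNA dopes into
light-emitting organic crystals of tris(8-hydroxyquinoline)aluminium
(Alq3). The package is aimed at molecular-simulation practitioners who have
trajectories of a DNA strand adsorbing onto an Alq3 cluster and want to
quantify the noncovalent interactions driving incorporation, plus the
optical measurements used to confirm the doping.

It provides four linked analyses:

1. **Interaction fingerprinting.** Per frame, π-π stacking between
   nucleobase rings and quinolinate ligand planes is detected with the
   geometric criterion *vertical separation < 0.45 nm*, where the vertical
   separation is the centroid displacement projected on the sign-aligned
   bisector of the two ring normals (a lateral guard on centroid distance
   rejects distant coplanar rings). Hydrogen bonds use the standard
   D–A ≤ 0.35 nm, ∠H–D–A ≤ 30° criteria. Each base-frame is then classified
   with fixed priority into:
   * **Type I multisite** — one Alq3 molecule provides both a stack and an
     H-bond to the same base (the thymine mode),
   * **Type II multisite** — H-bond to one Alq3, stack on a neighbouring
     Alq3 (the adenine mode),
   * **H-bond only**, **π-π only**, or **none**.
   Occurrence probabilities are each category's event count divided by the
   total non-none count; the module also reports stacked-base statistics
   and continuous/intermittent hydrogen-bond lifetimes.
2. **Binding free energy.** Self-consistent WHAM over harmonic umbrella
   windows (default protocol: 40 windows, 0.15 nm spacing,
   k = 1000 kJ mol⁻¹ nm⁻², 298.15 K) yields the potential of mean force
   W(z); the binding energy is ΔG = −[max W − min W], reported negative
   for favourable binding, with replicate mean ± sd.
3. **Photophysics.** Three-Gaussian deconvolution of photoluminescence
   spectra and the emission ratio A₅₇₂/A₅₁₂ (acceptor/donor band areas, the
   doping-degree proxy); FRET efficiency E = 1 − I_DA/I_D; exponential
   optical-waveguide loss fitting I(d) = I₀e^(−αd); fluorescence-profile
   normalization.
4. **Synthetic data.** Seeded generators that emulate each input with
   known ground truth — labeled interaction trajectories whose base
   geometries satisfy their scheduled mode by construction, exact biased
   umbrella samples from a known 1-D potential, Gaussian-sum spectra, and
   exponential decay series — so the full pipeline is testable without any
   MD engine.

## Worked example

Run the interaction survey on the default study conditions (a 20-mer
thymine-like strand against a 100-molecule Alq3 cluster, 500 frames at
2 ps, mode schedule 4% Type I / 2% Type II / 6% H-bond / 88% π-π):

```bash
python analysis/01_interaction_survey.py 1
```

```
analyzed 500 frames x 20 bases
 category  count  probability_pct
    TypeI    395             3.95
   TypeII    208             2.08
HbondOnly    607             6.07
   PiOnly   8790            87.90
classifier agreement with scheduled labels: 100.00%
stacked bases per frame: 18.79 +/- 1.09
mean continuous H-bond lifetime: 2.2 ps
```

The occurrence table is the per-category event count over all analysed
base-frames and its share of the non-none total (summing to 100%); with
noise-free geometry the classifier reproduces every scheduled label.
`analysis/02_binding_energy.py` stitches three replicate PMFs from a
50 kJ/mol Gaussian binding well and prints
`binding energy -50.14 +/- 0.17 kJ/mol`; `analysis/03_photophysics.py`
recovers the emission ratio 0.3000 from a 1%-noise spectrum generated with
0.30, the loss coefficient 0.03701 μm⁻¹ from a clean decay, and a 7.9% FRET
efficiency from donor intensities 100 and 92.1.

The same stages are scriptable through one CLI:

```bash
nucleodope run --config configs/demo.yaml --out out/
nucleodope synthesize umbrella --out windows.tsv
nucleodope analyze wham --windows windows.tsv --out pmf.tsv
nucleodope analyze binding --pmf pmf.tsv
```

## Layout

```
src/nucleodope/     library: model, io, definitions, geometry, contacts,
                    energetics, photophysics, synthetic, pipeline, cli
analysis/           numbered narrative drivers writing under results/
tests/              pytest suite incl. brute-force oracle checks
scripts/            acceptance.py
docs/methods.md     model assumptions, parameters, numerical choices
```
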