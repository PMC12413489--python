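# fishmarkers

Proteomic species-specific marker mining for fish meat authentication.

Species substitution — selling cheaper fish under the label of a dearer one —
is among the most common food frauds, and it is hardest to detect precisely
where it is most tempting: in processed products whose morphology, DNA and
native proteins have been degraded by cooking. `fishmarkers` implements a
peptide-level authentication workflow on tryptic digests of fish muscle,
combining two complementary mass-spectrometry views:

* **MALDI-TOF peak lists** (peptide mass fingerprints, singly charged ions in
  the 900–4500 m/z window): the package merges peaks across spectra by mass
  tolerance, applies a frequency threshold within each cohort, and mines m/z
  values exclusive to one species — or to one processing state (raw vs
  cooked) of a species.
* **LC-ESI-Q-TOF peptide identifications** (search-engine exports with
  sequences and protein assignments): the package mines *characteristic
  sequences* — peptides identified in every sample file of one cohort and in
  no sample of any compared cohort — and ranks the proteins contributing the
  most of them.
* **Cross-platform matching**: a MALDI marker at m/z `x` corresponds to a
  neutral peptide mass `M = x − m_H+`; the package matches these against
  computed monoisotopic peptide masses within ±0.3 Da, tying anonymous
  fingerprint markers to identified sequences.

A seeded synthetic-data generator produces complete studies (27 MALDI
spectra and 9 peptide tables per species × state, planted exclusive peaks,
in-silico tryptic digests of synthetic proteomes, detection dropout, m/z
jitter) with exact ground truth, so every mining stage is validated
end to end.

## The method

For one species × state cohort of `n = 27` spectra (3 individuals × 3
technical replicates × 3 spots), peaks from all spectra of one state are
pooled and merged by single-linkage on sorted m/z gaps (gap tolerance
0.1 Da). A consensus value is **frequent** when present in ≥ 23 of the
27 cohort spectra, and a frequent value is a **species-exclusive marker**
when no other species' frequent list contains a value within 0.1 Da (a
stricter mode also vetoes values seen in *any* other species' spectrum).
Raw and cooked analyses run independently; markers stable under cooking are
found post hoc by pairing the two panels, and **state-differential markers**
separate raw from cooked meat of the same species. Markers in the
intersection of the species-exclusive and state-differential panels
determine species and processing at once.

On the sequence side, a peptide is **characteristic** of a cohort when
identified in all 9 of its sample files and in none of the compared
cohorts' files; the four-way variant compares raw and cooked cohorts of two
species simultaneously. Peptide masses are monoisotopic
(`M = Σ residues + H₂O`, MH⁺ = M + 1.007276 Da), with in-silico tryptic
digestion (cleave after K/R except before P, ≤ 1 missed cleavage, length
7–30) and methionine oxidation (+15.994915 Da) supported throughout.

## Worked example

`examples/crossmatch_reference_panels.py` cross-matches the bundled carp
marker panels against the curated characteristic peptides:

```
raw carp: 3 of 7 MALDI markers have a peptide counterpart
  MALDI   1093.7 -> neutral  1092.693  GFTLPTTNSR             M= 1092.556  |d|=0.136  (Creatine kinase, muscle b)
  MALDI   1263.6 -> neutral  1262.593  VAFNQVADIMR            M= 1262.644  |d|=0.051  (LanC synthetase component C-like)
  MALDI   1309.7 -> neutral  1308.693  IDFDAFLPMLK            M= 1308.679  |d|=0.014  (Myosin light chain 3, skeletal muscle isoform)

cooked carp: 4 of 10 MALDI markers have a peptide counterpart
  ...
raw salmon markers matching carp peptides: 0 (expected none — the peptides are carp-characteristic)
```

Each line reads: the MALDI marker m/z, the neutral mass after subtracting
one proton, the peptide whose computed monoisotopic mass lies within 0.3 Da,
and the protein it derives from. Three raw-carp and four cooked-carp
fingerprint markers are thereby identified at sequence level; the raw-salmon
markers match none of the carp peptides, as exclusivity demands.

The other examples simulate studies and run the miners against planted
truth:

```sh
python examples/mine_maldi_markers.py           # 18/18 planted m/z markers recovered
python examples/mine_characteristic_sequences.py
python examples/preprocess_profile_spectrum.py  # centroiding, 98/98 apexes found
```

A thin CLI wraps the same pipeline for shell use:

```sh
fishmarkers simulate --seed 1 --outdir study/
fishmarkers run-all --manifest study/manifest.csv --outdir reports/
fishmarkers peptide-mass GFTLPTTNSR
```

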