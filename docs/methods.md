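# Methods

## Problem setting and data model

The package authenticates fish meat from tryptic digests measured two ways.
A **MALDI-TOF measurement** is a centroided peak list (m/z, intensity)
identified by `(species, state, individual, technical replicate, spot)`;
a complete cohort for one species × processing state is 27 spectra
(3 × 3 × 3). An **LC-ESI measurement** is a table of identified peptides
(flanked sequence, protein accession and name, optional mass) identified by
the same key without the spot; a complete cohort is 9 tables. All mining is
presence/absence-based: intensities are carried through I/O but never enter
a decision, because marker status is defined by *occurrence across
replicates*, not abundance.

## Peak grouping

Peaks representing the same ion in different spectra are merged by
single-linkage on sorted m/z gaps: pool all (spectrum, m/z) pairs of one
analysis, sort, and split where consecutive values differ by more than
`gap_tol`. This equals the connected components of the pairwise
|Δm/z| ≤ `gap_tol` graph (verified against a brute-force transitive-closure
oracle in the tests) and has no bin-edge artifacts. If one spectrum
contributes several peaks to a group, the peak closest to the group median
is kept (ties break to the lower m/z) and the leftovers are re-split
recursively; this bounds chaining and guarantees at most one member per
spectrum per group while conserving every input peak. The consensus m/z is
the member median.

`gap_tol` defaults to 0.1 Da: marker m/z values are conventionally reported
to one decimal, and with replicate jitter of ~0.03 Da (see the generator) a
0.1 Da tolerance captures >99 % of replicate peaks while keeping distinct
one-decimal values apart. A group count that is non-increasing in `gap_tol`
is a tested invariant.

## MALDI marker mining

Within a cohort, a consensus m/z is *frequent* when present in at least
`min_count` spectra. The threshold is stored as a fraction (default 23/27 ≈
0.852) so that cohorts of other sizes scale; 23-of-27 is its canonical
instantiation. Species-exclusive markers are mined per state:

* `list_exclusive` (default): a frequent value is a marker unless another
  species' *frequency-filtered* list holds a value within `match_tol`
  (default = `gap_tol`). This mirrors a workflow that first compiles
  per-species frequent lists and then compares lists.
* `strict`: additionally vetoes values present in any single spectrum of
  another species. Strict panels are provably subsets of list-exclusive
  panels (tested).

Raw and cooked analyses are fully independent; a marker stable under
cooking is detected only post hoc by `shared_raw_cooked`, a greedy
nearest-first pairing of the two panels within `match_tol` with each value
used once. State-differential markers (raw vs cooked of one species) are
frequent in one state and absent, within tolerance, from the same species'
other-state frequent list. The intersection of species-exclusive and
state-differential panels yields dual markers that determine species and
processing simultaneously.

Anti-monotonicity of panels in `min_count` holds on data where exclusive
peaks never recur in other species (as in the generator); with real cross
species near-coincidences a higher threshold can in principle *unmask* a
marker by dropping it from a competitor's list, which is why the threshold
is exposed rather than hard-coded.

## Mass arithmetic and digestion

Monoisotopic residue masses are pinned in code at 5-decimal precision
(G = 57.02146 … W = 186.07931), water = 18.010565 Da, proton =
1.007276 Da, methionine oxidation = +15.994915 Da. A peptide's neutral
mass is the residue sum plus one water; concatenation additivity
(`M(ab) = M(a) + M(b) − H₂O`) is property-tested, and agreement with
pyteomics is asserted to 5 × 10⁻⁴ Da on random peptides. Tryptic digestion
cleaves after K/R except before P (the classical search-engine rule), with
≤ 1 missed cleavage and a 7–30 residue reporting window by default;
zero-missed fragments concatenate exactly to the protein (tested on random
sequences).

Charge subtraction uses the physical proton mass even where legacy
workflows subtract exactly 1 Da; the ±0.3 Da cross-match tolerance absorbs
the 0.007 Da difference (tested), and `proton=1.0` reproduces the integer
arithmetic exactly.

## Sequence-level mining

A presence set maps each (modification-stripped, by default) core sequence
to the sample files containing it. A sequence is characteristic of a cohort
iff it appears in **all** of the cohort's files and in **none** of any
compared cohort's files — a deliberately strict two-sided rule with no
frequency slack, matching the all-nine-files convention for 9-sample
cohorts. "Characteristic" is always relative to the supplied cohorts. The
four-way variant runs each of four cohorts (two species × two states)
against the other three, so surviving sequences also pin down processing.
Collapsing oxidized and unmodified forms into one entry is the default
(oxidation is a sample-handling artifact); the strict option keeps them
distinct and can only increase the entry count (tested). A degenerate
peptide reported under several accessions is credited to each, with a
warning, so per-protein tallies may exceed the sequence total.

Per-protein reporting counts distinct core sequences per sample file (zero
when absent) and summarizes mean ± sample standard deviation (n−1) across
files; the confident-detection filter requires ≥ 2 distinct peptides in
every file of the cohort.

## Cross-platform matching

Each MALDI marker m/z maps to a neutral mass by subtracting one proton
(MALDI ions are assumed singly charged); every peptide whose computed mass
lies within ±`tol` (default 0.3 Da, boundary inclusive) is reported, sorted
by mass error. The matched-marker count tallies distinct markers, not
(marker, peptide) pairs, so collisions do not inflate it. The count is
non-decreasing in `tol` (tested).

## Synthetic data generator

The generator emulates the study design, not instrument physics. MALDI:
planted cohort-exclusive positions and shared background positions are
drawn uniformly in the 900–4500 Da window with ≥ 0.5 Da mutual separation
(> 3 × `gap_tol`, so tolerance grouping cannot merge truth classes);
backgrounds appear in every spectrum, planted peaks independently with
`detection_prob` (default 0.95), and uniform filler peaks top each spectrum
up to a count drawn from [80, 110]. Every emitted m/z receives Gaussian
jitter (σ = 0.03 Da, chosen so 0.1 Da grouping captures >99 % of
replicates); intensities are exponential (scale arbitrary — the miners are
presence-based). At ~90 filler peaks over 3600 Da, the chance that filler
reaches a 23-of-27 frequency in any group is negligible, which the
zero-false-marker checks confirm empirically.

LC-ESI: per-species proteomes are random sequences with ~10 % combined K/R
frequency (so zero-missed tryptic fragments average ~10 residues and fall
mostly in the 7–30 window), mixing species-unique "core" proteins,
proteins shared verbatim across species (conserved background that can
never be characteristic), and state-exclusive proteins emulating
thermostable proteins that surface mainly in cooked meat. Each cohort's
available peptide pool is the digest union of its active proteins; truth
sets are computed by exact set difference on these pools *before* dropout,
so at full detection the miners must reproduce them exactly (tested), and
under dropout recovered sets must be truth subsets. Peptides are detected
per sample file with `peptide_detection_prob`; methionine-containing
peptides are emitted oxidized with probability 0.2.

What the generator does not emulate: isotope envelopes, adducts,
ionization-efficiency and retention-time structure, correlated (e.g.
individual-specific) dropout, homologous-but-unequal proteins between
species, and search-engine misidentifications. Passing tests therefore
demonstrate the correctness of the mining logic under the stated sampling
assumptions, not robustness to those real-data effects.

## Problem sizes and numerical choices

Default validation runs use 6 species × 27 spectra (MALDI) and 2 species ×
2 states × 9 tables (LC-ESI), the full design the thresholds refer to; the
grouping stage handles the resulting ~15 000 peaks in well under a second.
All randomness flows from one `numpy` generator per run; reruns with the
same seed produce byte-identical files. Tolerance boundaries are inclusive
throughout (a Δ of exactly 0.3 Da matches; a gap of exactly `gap_tol` does
not split). Degenerate inputs: empty peak lists are accepted with a
warning, empty cohorts are parameter errors, and an empty marker panel
serializes as a header-only report that round-trips.

## Known limitations

* The preprocessing stage (moving-average smoothing, grey-opening baseline,
  MAD-based SNR picking with a top-110 cap) is an algorithmic stand-in for
  interactive spectrum processing; its parameters are not calibrated to any
  particular instrument or software, and the miners are agnostic to it.
* `list_exclusive` and `strict` answer subtly different questions when a
  near-threshold peak occurs in a competitor species; both are exposed
  because presence lists alone cannot distinguish biological absence from
  detection failure.
* Characteristic sequences are relative to the compared cohorts only; a
  panel mined from two species says nothing about a third.
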