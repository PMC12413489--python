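"""Cross-platform check of the bundled carp marker panels.

Computes the monoisotopic mass of each curated characteristic peptide,
subtracts one proton from every MALDI marker m/z, and reports which markers
coincide within +-0.3 Da — the two-platform consistency check for carp.
"""

from fishmarkers import count_matched_markers, match_markers, peptide_mass
from fishmarkers.io_meta import parse_flanked_sequence
from fishmarkers.reference import CARP_CHARACTERISTIC_PEPTIDES, SPECIES_MARKERS

for state in ("raw", "cooked"):
    panel = SPECIES_MARKERS[state]["carp"]
    peptides = [
        (parse_flanked_sequence(s)[1], (), prot)
        for s, _mass, prot in CARP_CHARACTERISTIC_PEPTIDES[state]
    ]
    matches = match_markers(panel, peptides, tol=0.3)
    print(f"\n{state} carp: {count_matched_markers(matches, panel)} of "
          f"{len(panel)} MALDI markers have a peptide counterpart")
    for m in matches:
        print(f"  MALDI {m.maldi_mz:8.1f} -> neutral {m.neutral_mass:9.3f}  "
              f"{m.peptide:<22s} M={m.peptide_mass:9.3f}  |d|={m.delta:.3f}  ({m.protein_name})")

salmon = SPECIES_MARKERS["raw"]["salmon"]
raw_seqs = [parse_flanked_sequence(s)[1] for s, _m, _p in CARP_CHARACTERISTIC_PEPTIDES["raw"]]
n = count_matched_markers(match_markers(salmon, raw_seqs, tol=0.3), salmon)
print(f"\nraw salmon markers matching carp peptides: {n} (expected none — "
      "the peptides are carp-characteristic)")
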