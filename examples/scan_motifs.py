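"""Scan a toy genome for canonical and non-canonical PQS motifs.

Builds a two-chromosome sequence containing one instance of each motif
class (on both strands), scans it, and prints the BED-style calls. The
name column carries the subtype; the score column the number of
G-tracts; minus-strand calls are reported in plus-strand coordinates.
"""

import sys

from quadprobe import SequenceRecord, scan_genome, subtype_combination_counts, write_bed

PLANTED = {
    "4G": "GGGAGGGTGGGAGGG",  # 4 tracts, 1-nt loops: the minimal canonical PQS
    "4GL15": "GGGAGGGTGGGTTTTTTTTTGGG",  # one 9-nt loop
    "GVBQ": "GGTGGGAGGGTGGG",  # terminal GG vacancy
    "Bulge": "GGGAGGAGTGGGAGGG",  # one tract broken by a single A
    "Hybrid3": "GGGAGGGTGGG",  # three tracts; needs RNA G-tracts to fold
}

spacer = "ATTATAATTTAATATT"
chr1 = spacer + spacer.join(PLANTED.values()) + spacer
# chr2 carries the reverse complements: everything should come back as "-"
rc = str.maketrans("ACGT", "TGCA")
chr2 = spacer + spacer.join(s.translate(rc)[::-1] for s in PLANTED.values()) + spacer

records = [SequenceRecord("chr1", chr1), SequenceRecord("chr2", chr2)]
motifs = scan_genome(records)

write_bed(motifs, sys.stdout)
print()
print("calls per subtype:")
for combo, count in subtype_combination_counts(motifs).items():
    print(f"  {combo:10s} {count}")
print()
print("Each planted motif is recovered once per strand; hybrid (2-3 tract)")
print("motifs count separately from the four intramolecular classes.")
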