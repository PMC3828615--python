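"""Quantify a small-RNA library: trim, filter, collapse, map, normalize.

Builds a 3-entry mature-miRNA reference and a toy library whose reads carry
a 3' adapter and up to two substitutions, then prints the per-miRNA counts
and reads-per-million (RPM).  The two mir205-derived reads differ by one
base and still map; the 10-nt fragment is discarded as too short.
"""

from mirmarker import Condition, ReadLibrary, quantify_libraries

reference = {
    "mir205": "TCCTTCATTCCACCGGAGTCTG",
    "mir143": "TGAGATGAAGCACTGTAGCTC",
    "mir21": "TAGCTTATCAGACTGATGTTGA",
}
ADAPTER = "TCGTATGCCGTCTTCTGCTTG"

reads = [
    reference["mir205"] + ADAPTER,            # exact
    "TCCTTCATTCCACCGGAGTCAG" + ADAPTER,       # mir205 with one substitution
    reference["mir143"] + ADAPTER,
    reference["mir143"] + ADAPTER,
    "TAGCTTATCA",                             # too short after trimming
]
library = ReadLibrary("tumor_01", Condition.TUMOR, reads)

table, results = quantify_libraries([library], reference, adapter=ADAPTER)
stats = results["tumor_01"].stats

print("per-miRNA raw counts:")
print(table.raw)
print("\nRPM (counts per million mapped):")
print(table.rpm.round(0))
print(f"\n{int(stats['input_reads'])} reads in, "
      f"{int(stats['short_discarded'])} discarded as <16 nt, "
      f"{int(stats['mapped'])} mapped (<=2 mismatches against the reference).")
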