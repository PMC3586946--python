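"""Detect maximal common cis-elements between two promoters' element sets.

A common cis-element is a distinct >= 6-nt string occurring in a putative
element of each promoter; substrings of a longer common string are not
counted separately (maximality), so one long shared run contributes one
entry at its own length instead of inflating every shorter length class.
"""

from comir import find_common_elements, length_spectrum

promoter_a = ["TTACGTACGTACGG", "GGGTTTAAACCC", "CATGCATG"]
promoter_b = ["ACGTACGTAC", "AATTTAAACG", "TTTTTTTT"]

common = find_common_elements(promoter_a, promoter_b)
print("maximal common elements:")
for el in common:
    print(f"  {el.sequence:12s} (length {el.length}) "
          f"witnesses a={el.occurrences_a} b={el.occurrences_b}")

spectrum = length_spectrum(common)
print("\nlength spectrum (length -> count of distinct common strings):")
print(f"  {spectrum.as_dict()}")
# ACGTACGTAC (10 nt) absorbs its own 6..9-mers; TTTAAAC comes from the
# second pair of elements. The spectrum is the statistic tested for
# significance against the resampling null.
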