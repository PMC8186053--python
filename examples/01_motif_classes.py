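"""Canonical motif classes: how many distinct repeat types exist.

Motifs that are rotations and/or reverse complements of one another
describe the same microsatellite, so they are grouped into one canonical
class named by its lexicographically smallest member.
"""

from ssr_atlas import enumerate_classes

total = 0
for k in range(1, 7):
    classes = enumerate_classes(k)
    total += len(classes)
    heads = ", ".join(c.representative for c in classes[:4])
    print(f"motif size {k}: {len(classes):3d} classes  (first: {heads}...)")
print(f"total over sizes 1-6: {total} classes")

print("\nthe AC orbit:", enumerate_classes(2)[0].members())
# Each line counts the distinct repeat types of that unit size; 501 is
# the complete catalogue a 1-6 bp survey can ever observe.
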