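"""Filter candidate building blocks for the virtual Biginelli reaction.

Candidate educts must be small (MW < 300 Da), polar (alogP < 2), free of
Br/I, and carry exactly one reactive functionality — either an aldehyde
or a 1,3-dicarbonyl motif.  Each rejection reports the first criterion
that failed.
"""

from catsom import FilterCriteria, filter_building_blocks, parse_smiles

candidates = [
    ("O=Cc1ccccc1", "benzaldehyde"),
    ("CC(=O)CC(=O)Nc1ccc(OC)cc1", "p-acetoacetaniside"),
    ("O=Cc1ccc(Br)cc1", "4-bromobenzaldehyde"),
    ("O=Cc1ccc(C=O)cc1", "terephthalaldehyde"),
    ("CCO", "ethanol"),
    ("CC(=O)CC(=O)C", "acetylacetone"),
]

kept, rejected = filter_building_blocks(
    [(parse_smiles(smi), name) for smi, name in candidates],
    FilterCriteria(),
)

print("kept:")
for block in kept:
    print(f"  {block.id:22s} role={block.role}")
print("rejected:")
for r in rejected:
    print(f"  {r.id:22s} reason: {r.reason}")

# Kept blocks are valid educts for the virtual reaction; the rejections
# show the filter logic: halogen content and duplicated reactive sites
# disqualify a block even if its size and lipophilicity are fine.
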