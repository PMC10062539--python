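"""Encode a single point mutation as the 42-value sequence feature vector.

The first 20 values flag the substitution (-1 = deleted residue, +1 =
incoming), the next 20 count residue types in a 19-residue window around
the site, and the last two carry the experimental temperature and pH.
"""

from ddgcv import MutationRecord, encode_mutation
from ddgcv.features import FEATURE_NAMES

seq = "ACDEFGHIKLMNPQRSTVWY"  # one of every residue, positions 1-20
rec = MutationRecord("TOY1", position=10, wt_residue="L", mut_residue="A",
                     ddg=1.2, temperature=25.0, ph=7.0)

fv = encode_mutation(rec, seq)
arr = fv.to_array()

print(f"mutation {rec.label} on {seq}")
nonzero = {FEATURE_NAMES[i]: int(v) for i, v in enumerate(arr[:20]) if v != 0}
print(f"mutation-code nonzeros: {nonzero}  (sum {int(arr[:20].sum())})")
print(f"window covers positions 1-19, composition sum = "
      f"{int(arr[20:40].sum())}")
print(f"count of Y inside the window: {int(arr[20 + 19])} "
      f"(position 20 lies outside the truncated window)")
print(f"temperature, pH = {arr[40]}, {arr[41]}")
# The -1/+1 pair marks which residue was lost and which gained; the window
# counts summarize local sequence context — together they are all the model
# ever sees about the mutation.
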