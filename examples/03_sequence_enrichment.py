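"""The sequence-enrichment (SeEn) transform on a worked example.

A user interacted with three compounds; after each one the transform
injects its most similar known neighbour, doubling the sequence length
and densifying the dataset while preserving the original order. The
validation and test items of a leave-one-out split are never enriched.
"""

from seenrec import (
    EnrichmentConfig,
    SequentialDataset,
    SimilarityTable,
    enrich_dataset,
    enrich_random,
    enrich_sequence,
    original_items,
    split_leave_one_out,
)

table = SimilarityTable({
    ("noradrenaline", "monoamine"): 0.836,
    ("bisdemethoxycurcumin", "clethodim"): 0.667,
    ("terretonin", "yanuthones"): 0.780,
})

sequence = ["noradrenaline", "bisdemethoxycurcumin", "terretonin"]
enriched = enrich_sequence(sequence, table, n=1)
print("enriched sequence:")
for e in enriched:
    tag = f"  <- injected after {e.anchor}" if e.anchor else ""
    print(f"  {e.item}{tag}")
print("stripping injected items recovers the source:",
      [i for i, _ in original_items(enriched)] == sequence)

control = enrich_random(sequence, ["a", "b", "c", "d", "e"] + sequence, n=1, seed=7)
print("\nrandom-injection control:", [e.item for e in control])

# train-only scope within a leave-one-out split
ds = SequentialDataset(sequences={"u": [
    ("noradrenaline", 1984), ("bisdemethoxycurcumin", 1998),
    ("terretonin", 2005), ("andrastin_A", 2010)]})
split = split_leave_one_out(ds)
out = enrich_dataset(split, EnrichmentConfig(n=1), table=table)
print("\ntrain (enriched):", [e.item for e in out.train["u"]])
print("validation (untouched):", out.val["u"][0])
print("test target (untouched):", out.test["u"][0])
print("model window multiplier:", out.max_seq_multiplier,
      "(a base window of 50 becomes 100 at n=1)")
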