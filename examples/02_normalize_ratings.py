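"""Normalize a crowd rating table into the per-image outcome variable.

Raters use a bounded 1..5 scale idiosyncratically, so ratings are z-scored
within each participant before averaging per image; the per-image mean
z-score is the aesthetic-pleasure outcome used by all association analyses.
"""

from neurocost import gen_raw_ratings, normalize_ratings

raw = gen_raw_ratings(image_ids=[f"img{i:03d}" for i in range(20)],
                      n_participants=50, images_per_participant=10,
                      scale_max=5, seed=0)
counts = raw.groupby("image_id").size()
print(f"raw table: {len(raw)} ratings, {counts.min()}-{counts.max()} "
      "raters per image (balanced assignment)")

normalized = normalize_ratings(raw)
print(normalized.table.head().to_string(index=False))
print("mean_z near 0 for random ratings: each image's score is the average "
      "of its raters' within-participant z-scores")
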