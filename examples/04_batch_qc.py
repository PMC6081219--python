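"""Flag unanalyzable samples: pool imbalance and overdispersed counts.

The main real-world failure mode of batch-relative normalization is a
scattered profile, usually from a large imbalance between the two primer
pools in the library. This compares per-sample QC on a clean default batch
and on a batch simulated with severe imbalance + overdispersion: the QC
statistic is the scaled median absolute deviation (MAD) of the normalized
profile, with samples above 0.5 marked unanalyzable.
"""

import ampliconcnv as ac
from ampliconcnv.detect import batch_qc
from ampliconcnv.normalize import normalize_batch

configs = ac.fixture_configs(seed=4)
for name in ("clean_diploid", "unanalyzable"):
    dataset, _ = ac.simulate_dataset(configs[name])
    qc = batch_qc(normalize_batch(dataset))
    print(f"{name}: MAD {qc['mad'].min():.2f}-{qc['mad'].max():.2f}, "
          f"pool ratio {qc['pool_ratio'].min():.2f}-{qc['pool_ratio'].max():.2f}, "
          f"{int((~qc['analyzable']).sum())}/{len(qc)} samples flagged unanalyzable")
print()
print("A flagged sample should be re-libraried or re-quantified, not CNV-called.")
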