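"""Compare replicate-handling strategies: mean vs median vs all-replicates.

Literature solubility values for the same molecule often disagree across
sources.  The training table can aggregate them by arithmetic mean (the
default, matching how the evaluation sets were built), by median, or keep
every replicate as its own training row.  The same seed protocol and test
sets are used for all three, so differences reflect the training table only.
"""

import solqspr as sq
from solqspr.curation import records_to_log_molar

study = sq.generate_study(seed=1)
log_records = records_to_log_molar(study.records)
results = sq.compare_strategies(
    log_records, study.descriptors,
    {"tight": study.test_tight, "loose": study.test_loose},
    sq.MlpConfig(n_hidden=25, l2_alpha=0.2, seed=0))

for strategy, by_set in results.items():
    print(f"strategy={strategy}:")
    for name, rep in by_set.items():
        print(f"  {name}: {rep}")

# Mean and median usually perform alike; training on all replicates gives
# contradictory targets for the same descriptor vector, which tends to
# hurt rather than help.
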