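"""Identity classification under the four train/test regimes.

Generates a reduced corpus, computes MPS feature vectors, and runs a linear
discriminant on 20 MPS principal components within-condition (leave-one-out)
and across conditions.  Accuracy is far above chance within the discomfort
condition and collapses when generalizing to pain cries -- the individual
signature does not transfer.
"""

import numpy as np

from crysig import (
    ClassifierSpec,
    EligibilityRule,
    GeneratorConfig,
    SCHEMES,
    binomial_vs_chance,
    classify_identity,
    generate_corpus,
    select_eligible,
)
from crysig.pipeline import corpus_mps_features

cfg = GeneratorConfig(
    n_babies=12,
    pain_per_baby=4,
    discomfort_count_range=(6, 8),
    duration_mean_s=2.5,
    duration_sd_s=0.3,
    sample_rate=11025,
    seed=5,
)
recordings, metadata = generate_corpus(cfg)
features = corpus_mps_features(recordings)

rule = EligibilityRule()
for name in ("within-discomfort", "mixed", "cross", "within-pain"):
    scheme = SCHEMES[name]
    eligible = select_eligible(metadata, rule, scheme)
    mask = np.isin(features.baby_ids, eligible)
    report = classify_identity(features.subset(mask), ClassifierSpec(), scheme)
    p = binomial_vs_chance(report.correct_count, report.total_count, report.chance_level)
    print(
        f"{name:>18}: {report.correct_count}/{report.total_count} correct "
        f"({100 * report.accuracy:.1f}%), mean posterior "
        f"{100 * report.mean_diag_posterior:.1f}% ± {100 * report.diag_posterior_2se:.1f}, "
        f"chance {100 * report.chance_level:.1f}%, binomial p = {p:.2g}"
    )
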