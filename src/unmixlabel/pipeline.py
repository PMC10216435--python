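"""End-to-end phantom experiment: generate, label, train, classify, score.

This driver reproduces the study protocol on synthetic cohorts: a
patient-level 80/20 split, per-strategy label assignment on the training
patches, a weighted kNN model per strategy, pixel-wise classification of
the test patches with the 10-of-100 vote rule, and a metrics report per
strategy. The same split is reused across strategies so the comparison
is paired.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .classifier import classify_patch, split_by_patient, train_knn
from .evaluation import MetricsReport, metrics_report
from .labeling import STRATEGIES, assign_label
from .phantom import PhantomConfig, PhantomDataset, make_dataset


@dataclass
class ExperimentResult:
    reports: dict[str, MetricsReport]
    n_train: int
    n_test: int
    dataset: PhantomDataset

    def to_frame(self) -> pd.DataFrame:
        """Comparison-table view, one row per labeling strategy."""
        rows = []
        for name, rep in self.reports.items():
            rows.append(
                {
                    "strategy": name,
                    "sensitivity": rep.sensitivity,
                    "specificity": rep.specificity,
                    "accuracy": rep.accuracy,
                    "mcc": rep.mcc,
                    "auc": rep.auc,
                }
            )
        return pd.DataFrame(rows).set_index("strategy")


def run_experiment(
    config: PhantomConfig | None = None,
    seed: int = 0,
    strategies: tuple[str, ...] = STRATEGIES,
    vote_threshold: int | None = None,
) -> ExperimentResult:
    """Run the full protocol on one seeded phantom cohort."""
    config = config or PhantomConfig()
    if vote_threshold is None:
        vote_threshold = config.vote_threshold
    ss = np.random.SeedSequence([seed, 0xE5])
    data_seed, split_seed = (int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(2))

    ds = make_dataset(config, data_seed)
    train, test = split_by_patient(ds.patches, config.train_fraction, seed=split_seed)
    truth = [p.he_label for p in test]

    reports: dict[str, MetricsReport] = {}
    for strategy in strategies:
        labeled = [assign_label(strategy, p, ds.endmembers) for p in train]
        model = train_knn(labeled)
        preds, scores = [], []
        for patch in test:
            pp = classify_patch(model, patch, vote_threshold=vote_threshold)
            preds.append(pp.patch_label)
            scores.append(pp.patch_score)
        reports[strategy] = metrics_report(preds, truth, scores, strategy=strategy)
    return ExperimentResult(reports, n_train=len(train), n_test=len(test), dataset=ds)
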