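"""Reader-study evaluation arithmetic and segmentation-quality metrics.

The packaged fixture transcribes a 10-case reader study: a gold-standard
surgical plan (procedure and number of fibroids to be removed, by type)
plus two gynecologists' independent interpretations of each case from 2D
sagittal images and from 3D surface-rendered (SR) images, and per-observer
summary statistics (mean ± SD over the 10 cases) of interpretation time
and a 4-point difficulty score.

Accuracy is concordance with the gold standard (fraction of cases where
the observer's call equals it).  Times and difficulty are compared between
the two viewing methods with an unpaired two-sample t test computed from
the printed summary statistics; the pooled-variance (Student) form is the
default, Welch is available.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, stats

PROCEDURES = ("AM", "LAM", "TLM", "TCR")
OBSERVERS = ("observer1", "observer2")
METHODS = ("sagittal", "sr")

#: sha256 of the packaged fixture; load_fixtures refuses corrupted data
_FIXTURE_SHA256 = "c7c9a514aa3956d3a23f57c0a3a57260a38e1031523e3e2f7448caeb59a75ef0"


class FixtureIntegrityError(RuntimeError):
    """Packaged reader-study fixture does not match its checksum."""


@dataclass(frozen=True)
class SummaryStats:
    """Mean, standard deviation and group size of one measurement group."""

    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be non-negative")
        if self.n < 2:
            raise ValueError("summary statistics need n >= 2")


class ReaderStudyTable:
    """The study data: per-case records plus per-observer summaries."""

    def __init__(self, payload: dict):
        self.cases = payload["cases"]
        self.summaries = payload["summaries"]
        self._validate()

    def _validate(self) -> None:
        for case in self.cases:
            assert case["gold"]["procedure"] in PROCEDURES
            for obs in OBSERVERS:
                for method in METHODS:
                    rec = case[obs][method]
                    assert rec["procedure"] in PROCEDURES and rec["count"] >= 0

    @property
    def n_cases(self) -> int:
        return len(self.cases)

    def gold_procedures(self) -> list[str]:
        return [c["gold"]["procedure"] for c in self.cases]

    def gold_counts(self) -> list[int]:
        return [sum(c["gold"]["removals"].values()) for c in self.cases]

    def gold_removals_by_type(self) -> dict[str, int]:
        totals = {"intramural": 0, "subserosal": 0, "submucosal": 0}
        for c in self.cases:
            for k, v in c["gold"]["removals"].items():
                totals[k] += v
        return totals

    def observer_procedures(self, observer: str, method: str) -> list[str]:
        return [c[observer][method]["procedure"] for c in self.cases]

    def observer_counts(self, observer: str, method: str) -> list[int]:
        return [c[observer][method]["count"] for c in self.cases]

    def summary(self, measure: str, observer: str, method: str) -> SummaryStats:
        s = self.summaries[measure][observer][method]
        return SummaryStats(s["mean"], s["sd"], s["n"])


def load_fixtures() -> ReaderStudyTable:
    """Load the packaged study transcription, verifying its checksum."""
    raw = resources.files("fibroid3d.data").joinpath("reader_study.json").read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != _FIXTURE_SHA256:
        raise FixtureIntegrityError(
            f"reader_study.json checksum {digest} != expected {_FIXTURE_SHA256}"
        )
    return ReaderStudyTable(json.loads(raw))


def concordance_rate(observer_values: Sequence, gold_values: Sequence) -> float:
    """Fraction of positions where the observer's value equals the gold
    standard exactly (the study's accuracy rate)."""
    if len(observer_values) != len(gold_values):
        raise ValueError(
            f"length mismatch: {len(observer_values)} observer vs {len(gold_values)} gold"
        )
    if len(gold_values) == 0:
        raise ValueError("need at least one value")
    matches = sum(o == g for o, g in zip(observer_values, gold_values))
    return matches / len(gold_values)


def t_test_from_summary(
    g1: SummaryStats,
    g2: SummaryStats,
    welch: bool = False,
) -> tuple[float, float, float]:
    """Unpaired two-sample t test from summary statistics.

    Returns ``(t, df, two-sided p)``.  Default is the pooled-variance
    Student test; ``welch=True`` drops the equal-variance assumption
    (Welch-Satterthwaite degrees of freedom).
    """
    res = stats.ttest_ind_from_stats(
        g1.mean, g1.sd, g1.n, g2.mean, g2.sd, g2.n, equal_var=not welch
    )
    if welch:
        v1, v2 = g1.sd**2 / g1.n, g2.sd**2 / g2.n
        df = (v1 + v2) ** 2 / (v1**2 / (g1.n - 1) + v2**2 / (g2.n - 1))
    else:
        df = g1.n + g2.n - 2
    return float(res.statistic), float(df), float(res.pvalue)


def segmentation_metrics(
    pred: np.ndarray,
    truth: np.ndarray,
    spacing: Sequence[float] = (1.0, 1.0, 1.0),
) -> tuple[float, float]:
    """Dice overlap and symmetric Hausdorff distance (mm) between masks.

    Dice = 2|A∩B| / (|A|+|B|); Hausdorff is the larger of the two directed
    maximum voxel-center-to-nearest-voxel-center distances, computed on the
    anisotropic grid via Euclidean distance transforms.  Two empty masks
    are a perfect match (Dice 1, Hausdorff 0); one empty mask gives Dice 0
    and an infinite Hausdorff distance.
    """
    pred = np.asarray(pred, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if pred.shape != truth.shape:
        raise ValueError(f"grid mismatch: {pred.shape} vs {truth.shape}")
    a, b = int(pred.sum()), int(truth.sum())
    if a == 0 and b == 0:
        return 1.0, 0.0
    if a == 0 or b == 0:
        return 0.0, float("inf")
    inter = int((pred & truth).sum())
    dice = 2.0 * inter / (a + b)
    spacing = tuple(float(s) for s in spacing)
    d_to_truth = ndimage.distance_transform_edt(~truth, sampling=spacing)
    d_to_pred = ndimage.distance_transform_edt(~pred, sampling=spacing)
    hausdorff = max(float(d_to_truth[pred].max()), float(d_to_pred[truth].max()))
    return dice, hausdorff


def make_table4(table: ReaderStudyTable | None = None) -> pd.DataFrame:
    """Concordance rates of both observers, both viewing methods and both
    measures (procedure choice and fibroid count) against the gold standard.

    Rows are the two measures, columns a (observer, method) MultiIndex,
    values fractions in [0, 1].
    """
    if table is None:
        table = load_fixtures()
    gold_proc = table.gold_procedures()
    gold_count = table.gold_counts()
    data = {}
    for obs in OBSERVERS:
        for method in METHODS:
            data[(obs, method)] = [
                concordance_rate(table.observer_procedures(obs, method), gold_proc),
                concordance_rate(table.observer_counts(obs, method), gold_count),
            ]
    frame = pd.DataFrame(
        data,
        index=pd.Index(["surgical_procedure", "fibroid_count"], name="measure"),
    )
    frame.columns = pd.MultiIndex.from_tuples(frame.columns, names=["observer", "method"])
    return frame


def summary_ttests(table: ReaderStudyTable | None = None, welch: bool = False) -> pd.DataFrame:
    """t tests comparing sagittal vs SR viewing per observer, for the
    interpretation-time and difficulty summaries."""
    if table is None:
        table = load_fixtures()
    rows = []
    for measure in ("required_time_s", "difficulty_score"):
        for obs in OBSERVERS:
            g1 = table.summary(measure, obs, "sagittal")
            g2 = table.summary(measure, obs, "sr")
            t, df, p = t_test_from_summary(g1, g2, welch=welch)
            rows.append(
                {
                    "measure": measure,
                    "observer": obs,
                    "sagittal_mean": g1.mean,
                    "sagittal_sd": g1.sd,
                    "sr_mean": g2.mean,
                    "sr_sd": g2.sd,
                    "t": t,
                    "df": df,
                    "p": p,
                }
            )
    return pd.DataFrame(rows)
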