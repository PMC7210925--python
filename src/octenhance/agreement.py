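"""Intergrader agreement statistics for biomarker grading studies.

Two masked graders assess each B-scan twice (original and enhanced
condition), flagging the presence of retinal biomarkers and scoring
subjective quality from 1 to 10. This module computes Cohen's kappa per
biomarker and condition, and compares the quality scores between
conditions with a Wilcoxon signed-rank test. No inferential comparison
between kappas is computed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateInputError, InputError

#: the graded biomarkers, in CSV column order
BIOMARKERS = ("IRF", "SRF", "ERM", "Drusen", "RPD", "GA", "iRORA", "PED", "HE", "SCAR_FIB")
CONDITIONS = ("original", "enhanced")
CSV_COLUMNS = ("image_id", "grader_id", "condition", *BIOMARKERS, "quality")


@dataclass(frozen=True)
class AgreementResult:
    """Chance-corrected agreement for one biomarker under one condition."""

    biomarker: str
    condition: str
    kappa: float
    n: int
    observed_agreement: float
    chance_agreement: float


def cohens_kappa(labels_a: Sequence, labels_b: Sequence) -> tuple[float, float, float]:
    """Cohen's kappa between two raters: (kappa, p_o, p_e).

    kappa = (p_o - p_e) / (1 - p_e); when both raters are constant and
    identical (p_e = 1) kappa is defined as 1.
    """
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape or a.ndim != 1:
        raise InputError("label lists must be equal-length 1-D sequences")
    n = len(a)
    if n < 1:
        raise InputError("label lists are empty")
    cats = np.unique(np.concatenate([a, b]))
    ai = np.searchsorted(cats, a)
    bi = np.searchsorted(cats, b)
    k = len(cats)
    table = np.zeros((k, k))
    np.add.at(table, (ai, bi), 1.0)
    p_o = float(np.trace(table)) / n
    p_e = float(table.sum(axis=1) @ table.sum(axis=0)) / n**2
    if p_e >= 1.0:
        return 1.0, p_o, p_e
    return (p_o - p_e) / (1.0 - p_e), p_o, p_e


def wilcoxon_quality(pre: Sequence[float], post: Sequence[float]) -> tuple[float, float]:
    """Wilcoxon signed-rank test on paired quality scores.

    Zero differences are dropped; tied absolute differences receive
    midranks. The statistic is the smaller of the positive and negative
    rank sums. The p-value is exact (full sign-flip distribution, computed
    by convolution over the ranks, so ties are handled) for n <= 25 pairs
    after zero removal, and a tie-corrected normal approximation otherwise.
    Two-sided.
    """
    x = np.asarray(pre, dtype=np.float64)
    y = np.asarray(post, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise InputError("pre/post must be equal-length 1-D sequences")
    d = y - x
    d = d[d != 0]
    n = len(d)
    if n == 0:
        raise DegenerateInputError("all paired differences are zero")
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    statistic = min(w_plus, w_minus)
    if n <= 25:
        p = _exact_signflip_p(ranks, statistic)
    else:
        total = n * (n + 1) / 4.0
        _, counts = np.unique(ranks, return_counts=True)
        tie_term = float((counts**3 - counts).sum()) / 48.0
        var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
        if var <= 0:
            raise DegenerateInputError("zero variance in signed-rank statistic")
        z = (statistic - total) / np.sqrt(var)
        p = float(min(1.0, 2.0 * stats.norm.cdf(z)))
    return statistic, p


def _exact_signflip_p(ranks: np.ndarray, statistic: float) -> float:
    """Exact two-sided p: distribution of the positive rank sum over all
    2^n sign assignments, via polynomial convolution on doubled ranks
    (midranks are half-integers, so doubling makes them integral)."""
    r2 = np.round(2 * ranks).astype(int)
    total = int(r2.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    s2 = int(round(2 * statistic))
    cdf = counts[: s2 + 1].sum() / counts.sum()
    return float(min(1.0, 2.0 * cdf))


def flip_model_kappa(q: float, prevalence: float) -> float:
    """Analytic Cohen's kappa when two graders each flip the true binary
    label independently with probability ``q``.

    Agreement requires both graders to flip or neither, so
    p_o = (1-q)^2 + q^2 regardless of prevalence; the marginal presence
    rate is m = prevalence*(1-q) + (1-prevalence)*q and
    p_e = m^2 + (1-m)^2.
    """
    p_o = (1 - q) ** 2 + q**2
    m = prevalence * (1 - q) + (1 - prevalence) * q
    p_e = m**2 + (1 - m) ** 2
    if p_e >= 1.0:
        return 1.0
    return (p_o - p_e) / (1.0 - p_e)


def simulate_grading_records(
    n_images: int,
    flip_prob: dict[str, float] | float = 0.1,
    prevalence: float = 0.3,
    quality_shift: float = 2.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Synthetic two-grader study under a planted label-flip model.

    Each image has a true presence flag per biomarker (Bernoulli
    ``prevalence``); each grader reports it flipped with probability
    ``flip_prob`` (scalar, or per-condition dict with keys 'original' and
    'enhanced'). Quality scores are integers in 1..10: original around 5,
    enhanced shifted up by ``quality_shift`` on average, emulating the
    perceived-quality improvement a real study reports.
    """
    rng = np.random.default_rng(seed)
    if not isinstance(flip_prob, dict):
        flip_prob = {c: float(flip_prob) for c in CONDITIONS}
    truth = {b: rng.random(n_images) < prevalence for b in BIOMARKERS}
    q_orig = np.clip(np.round(rng.normal(5.0, 1.5, n_images)), 1, 10).astype(int)
    rows = []
    for condition in CONDITIONS:
        q = flip_prob[condition]
        if condition == "enhanced":
            qual_base = np.clip(
                q_orig + np.round(rng.normal(quality_shift, 1.0, n_images)), 1, 10
            ).astype(int)
        else:
            qual_base = q_orig
        for grader in ("grader_1", "grader_2"):
            flips = {b: rng.random(n_images) < q for b in BIOMARKERS}
            qual = np.clip(
                qual_base + rng.integers(-1, 2, n_images), 1, 10
            ).astype(int)
            for i in range(n_images):
                row = {"image_id": f"img{i:05d}", "grader_id": grader,
                       "condition": condition, "quality": int(qual[i])}
                for b in BIOMARKERS:
                    row[b] = bool(truth[b][i] ^ flips[b][i])
                rows.append(row)
    return pd.DataFrame(rows)[list(CSV_COLUMNS)]


def read_grading_csv(path) -> pd.DataFrame:
    """Read a grading table; the named columns are required, extras ignored."""
    table = pd.read_csv(path)
    missing = [c for c in CSV_COLUMNS if c not in table.columns]
    if missing:
        raise InputError(f"grading CSV missing columns: {missing}")
    return validate_records(table[list(CSV_COLUMNS)])


def validate_records(records: pd.DataFrame) -> pd.DataFrame:
    """Check the grading-record invariants; returns the validated frame."""
    records = records.copy()
    bad_cond = set(records["condition"]) - set(CONDITIONS)
    if bad_cond:
        raise InputError(f"unknown condition values: {sorted(bad_cond)}")
    q = records["quality"]
    if not np.all((q >= 1) & (q <= 10) & (q == q.astype(int))):
        raise InputError("quality scores must be integers in 1..10")
    for b in BIOMARKERS:
        vals = set(pd.unique(records[b]))
        if not vals <= {0, 1, True, False}:
            raise InputError(f"biomarker {b} has non-boolean values: {sorted(map(str, vals))}")
        records[b] = records[b].astype(bool)
    return records


def agreement_report(records: pd.DataFrame) -> dict:
    """Per-biomarker kappa for each condition plus quality summaries.

    Requires exactly two graders and full coverage: every
    (image_id, condition) graded by both. Returns a dict with a tidy
    ``agreement`` DataFrame (biomarkers x 2 conditions rows), per-grader
    quality histograms, and the original-vs-enhanced Wilcoxon per grader.
    A pure function of the input table.
    """
    records = validate_records(records)
    graders = sorted(pd.unique(records["grader_id"]))
    if len(graders) != 2:
        raise InputError(f"need exactly 2 graders, found {len(graders)}: {graders}")
    cover = records.groupby(["image_id", "condition"])["grader_id"].nunique()
    offenders = cover[cover < 2]
    if len(offenders):
        raise InputError(
            "images missing a grader: "
            + ", ".join(f"{i}/{c}" for i, c in offenders.index[:20])
        )

    rows = []
    for condition in CONDITIONS:
        sub = records[records["condition"] == condition]
        a = sub[sub["grader_id"] == graders[0]].sort_values("image_id")
        b = sub[sub["grader_id"] == graders[1]].sort_values("image_id")
        for biomarker in BIOMARKERS:
            kappa, p_o, p_e = cohens_kappa(a[biomarker].to_numpy(), b[biomarker].to_numpy())
            rows.append(AgreementResult(biomarker, condition, kappa, len(a), p_o, p_e))
    agreement = pd.DataFrame([r.__dict__ for r in rows])

    quality: dict[str, dict] = {}
    for grader in graders:
        sub = records[records["grader_id"] == grader]
        orig = sub[sub["condition"] == "original"].sort_values("image_id")["quality"]
        enh = sub[sub["condition"] == "enhanced"].sort_values("image_id")["quality"]
        entry: dict = {
            "histogram_original": orig.value_counts().reindex(range(1, 11), fill_value=0),
            "histogram_enhanced": enh.value_counts().reindex(range(1, 11), fill_value=0),
            "mean_original": float(orig.mean()),
            "mean_enhanced": float(enh.mean()),
        }
        try:
            stat, p = wilcoxon_quality(orig.to_numpy(), enh.to_numpy())
            entry["wilcoxon_statistic"] = stat
            entry["wilcoxon_p"] = p
        except DegenerateInputError:
            entry["wilcoxon_statistic"] = float("nan")
            entry["wilcoxon_p"] = float("nan")
        quality[str(grader)] = entry

    return {"agreement": agreement, "quality": quality}
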