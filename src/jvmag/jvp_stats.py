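"""Agreement statistics for paired noninvasive vs invasive JVP measurements.

The comparison scheme: per participant, rater assessments are averaged
within each modality; pressures (cm H2O) are mapped to the three clinical
volume-status categories

* ``normal``     — value <= 7
* ``borderline`` — 7 < value <= 10
* ``elevated``   — value > 10

and each noninvasive category is compared with the right-heart-
catheterization (RHC) category: agreement, one-category (partial) or
two-category (complete) disagreement.  The category counts are tested with
a Pearson chi-square against a uniform expectation, and the raw paired
pressures are summarized by the mean difference, its Student-t 95%
confidence interval, and a two-sided Wilcoxon signed-rank test (zeros
dropped; exact rank-sum distribution up to n = 25, normal approximation
with continuity and tie correction beyond).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as _stats

__all__ = [
    "MODALITIES",
    "CATEGORIES",
    "AgreementTable",
    "PairedSummary",
    "ChiSqResult",
    "average_raters",
    "classify_jvp",
    "agreement_level",
    "tabulate_agreement",
    "chisq_uniform",
    "paired_summary",
    "wilcoxon_signed_rank_p",
    "run_study_analysis",
]

MODALITIES = ("bedside", "unamplified", "amplified", "rhc")
CATEGORIES = ("normal", "borderline", "elevated")
_RANK = {c: i for i, c in enumerate(CATEGORIES)}

NORMAL_MAX = 7.0  # cm H2O, inclusive
BORDERLINE_MAX = 10.0  # cm H2O, inclusive


@dataclass
class AgreementTable:
    """Counts of 0-, 1- and 2-category discrepancies vs RHC."""

    n_agree: int
    n_disagree1: int
    n_disagree2: int

    @property
    def total(self) -> int:
        return self.n_agree + self.n_disagree1 + self.n_disagree2

    @property
    def counts(self) -> tuple[int, int, int]:
        return (self.n_agree, self.n_disagree1, self.n_disagree2)

    def percentages(self) -> dict:
        """Each category as percent of pairs, one decimal and nearest int."""
        out = {}
        for name, c in zip(("agree", "disagree1", "disagree2"), self.counts):
            pct = 100.0 * c / self.total
            out[name] = {"pct": round(pct, 1), "pct_int": int(round(pct))}
        return out


@dataclass
class PairedSummary:
    mean_diff: float
    ci_low: float
    ci_high: float
    wilcoxon_p: float
    n: int


@dataclass
class ChiSqResult:
    statistic: float
    df: int
    p: float
    observed: tuple
    expected: tuple


def average_raters(measurements: pd.DataFrame) -> pd.DataFrame:
    """Mean value per participant x modality (arithmetic mean over raters).

    Expects columns ``participant_id, modality, rater_id, value_cmH2O``;
    returns a tidy frame with one row per participant-modality.
    """
    required = {"participant_id", "modality", "value_cmH2O"}
    missing = required - set(measurements.columns)
    if missing:
        raise ValueError(f"measurement table lacks columns: {sorted(missing)}")
    unknown = set(measurements["modality"]) - set(MODALITIES)
    if unknown:
        raise ValueError(
            f"unknown modalities {sorted(unknown)}; expected one of {MODALITIES}"
        )
    values = measurements["value_cmH2O"].to_numpy(dtype=float)
    if not np.isfinite(values).all():
        raise ValueError("measurement values must be finite")
    return (
        measurements.groupby(["participant_id", "modality"], as_index=False)[
            "value_cmH2O"
        ]
        .mean()
        .rename(columns={"value_cmH2O": "mean_value_cmH2O"})
    )


def classify_jvp(value: float) -> str:
    """Map a pressure (cm H2O) to normal / borderline / elevated."""
    if not np.isfinite(value) or value < 0:
        raise ValueError(f"pressure must be finite and >= 0, got {value}")
    if value <= NORMAL_MAX:
        return "normal"
    if value <= BORDERLINE_MAX:
        return "borderline"
    return "elevated"


def agreement_level(cat_a: str, cat_b: str) -> int:
    """Ordinal distance between two volume-status categories (0, 1 or 2)."""
    try:
        return abs(_RANK[cat_a] - _RANK[cat_b])
    except KeyError as exc:
        raise ValueError(f"unknown category {exc.args[0]!r}") from exc


def tabulate_agreement(
    noninvasive: np.ndarray, rhc: np.ndarray
) -> AgreementTable:
    """Classify both members of each participant pair and count discrepancies."""
    noninvasive = np.asarray(noninvasive, dtype=float)
    rhc = np.asarray(rhc, dtype=float)
    if noninvasive.shape != rhc.shape or noninvasive.ndim != 1:
        raise ValueError("inputs must be equal-length 1-D paired arrays")
    if len(noninvasive) == 0:
        raise ValueError("no pairs to tabulate")
    counts = [0, 0, 0]
    for a, b in zip(noninvasive, rhc):
        counts[agreement_level(classify_jvp(a), classify_jvp(b))] += 1
    return AgreementTable(*counts)


def chisq_uniform(table: AgreementTable) -> ChiSqResult:
    """Pearson chi-square of the agreement counts against uniformity.

    The null expectation splits the pairs evenly over the three
    discrepancy categories; df = 2.
    """
    observed = np.asarray(table.counts, dtype=float)
    total = observed.sum()
    if total < 1:
        raise ValueError("agreement table is empty")
    expected = np.full(3, total / 3.0)
    stat, p = _stats.chisquare(observed, f_exp=expected)
    return ChiSqResult(
        statistic=float(stat),
        df=2,
        p=float(p),
        observed=tuple(int(c) for c in table.counts),
        expected=tuple(expected),
    )


def _signed_rank_exact_p(d: np.ndarray) -> float:
    """Exact two-sided signed-rank p by convolution over the rank-sum DP.

    Ties receive midranks; doubling the ranks makes them integers so the
    null distribution of ``W+`` (sum of positive ranks) is built by
    polynomial convolution over all 2^n equally likely sign assignments.
    """
    ranks = _stats.rankdata(np.abs(d))
    r2 = np.rint(2 * ranks).astype(int)  # midranks doubled -> integers
    total = int(r2.sum())
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for r in r2:
        nxt = dist.copy()
        nxt[r:] += dist[: total + 1 - r]
        dist = nxt
    dist /= dist.sum()
    w_plus = int(np.rint(2 * ranks[d > 0].sum()))
    cdf = np.cumsum(dist)
    p_low = cdf[w_plus]
    p_high = 1.0 - (cdf[w_plus - 1] if w_plus > 0 else 0.0)
    return float(min(1.0, 2.0 * min(p_low, p_high)))


def wilcoxon_signed_rank_p(differences: np.ndarray, exact_max_n: int = 25) -> float:
    """Two-sided Wilcoxon signed-rank p on paired differences.

    Zero differences are dropped (Wilcoxon's rule).  With at most
    ``exact_max_n`` nonzero differences, the exact sign-flip null
    distribution is used (handles ties via midranks); otherwise the
    normal approximation with continuity and tie correction.
    """
    d = np.asarray(differences, dtype=float)
    d = d[d != 0]
    if len(d) == 0:
        return 1.0
    if len(d) <= exact_max_n:
        return _signed_rank_exact_p(d)
    return float(
        _stats.wilcoxon(
            d, zero_method="wilcox", correction=True, alternative="two-sided",
            method="approx",
        ).pvalue
    )


def paired_summary(
    noninvasive: np.ndarray, rhc: np.ndarray, confidence: float = 0.95
) -> PairedSummary:
    """Mean difference (noninvasive - RHC), t-based CI and Wilcoxon p."""
    noninvasive = np.asarray(noninvasive, dtype=float)
    rhc = np.asarray(rhc, dtype=float)
    if noninvasive.shape != rhc.shape or noninvasive.ndim != 1:
        raise ValueError("inputs must be equal-length 1-D paired arrays")
    n = len(noninvasive)
    if n < 2:
        raise ValueError("paired summary needs at least 2 pairs")
    d = noninvasive - rhc
    mean = float(d.mean())
    if np.allclose(d, 0):
        return PairedSummary(0.0, 0.0, 0.0, 1.0, n)
    sem = d.std(ddof=1) / np.sqrt(n)
    tcrit = _stats.t.ppf(0.5 + confidence / 2, df=n - 1)
    return PairedSummary(
        mean_diff=mean,
        ci_low=mean - tcrit * sem,
        ci_high=mean + tcrit * sem,
        wilcoxon_p=wilcoxon_signed_rank_p(d),
        n=n,
    )


def run_study_analysis(
    measurements: pd.DataFrame, out_dir: str | Path | None = None
) -> dict:
    """Full measurement-comparison report for one study table.

    Averages raters, pairs each noninvasive modality with RHC by
    participant (unpaired participants are dropped and reported), and
    produces descriptive statistics, paired summaries, agreement tables
    and chi-square results.  With ``out_dir``, writes ``descriptives.csv``,
    ``tables3_4.csv`` and ``summary.txt``.
    """
    means = average_raters(measurements)
    wide = means.pivot(
        index="participant_id", columns="modality", values="mean_value_cmH2O"
    )
    if "rhc" not in wide.columns:
        raise ValueError("no 'rhc' measurements: nothing to compare against")

    report: dict = {"descriptives": {}, "paired": {}, "agreement": {}, "dropped": {}}
    for m in MODALITIES:
        if m not in wide.columns:
            continue
        vals = wide[m].dropna()
        report["descriptives"][m] = {
            "n": int(vals.size),
            "mean": float(vals.mean()),
            "sd": float(vals.std(ddof=1)) if vals.size > 1 else float("nan"),
            "iqr": (
                float(vals.quantile(0.25)),
                float(vals.quantile(0.75)),
            ),
        }

    rows = []
    for m in ("bedside", "unamplified", "amplified"):
        if m not in wide.columns:
            continue
        paired = wide[[m, "rhc"]].dropna()
        report["dropped"][m] = int(len(wide) - len(paired))
        x = paired[m].to_numpy()
        y = paired["rhc"].to_numpy()
        if len(paired) >= 2:
            ps = paired_summary(x, y)
            report["paired"][m] = ps
        else:
            ps = None
            report["paired"][m] = (
                f"skipped: {len(paired)} pair(s); paired tests need n >= 2"
            )
        at = tabulate_agreement(x, y) if len(paired) >= 1 else None
        chi = chisq_uniform(at) if at else None
        report["agreement"][m] = {"table": at, "chisq": chi}
        rows.append(
            {
                "modality": m,
                "n_pairs": len(paired),
                "mean_diff_cmH2O": ps.mean_diff if ps else np.nan,
                "ci_low": ps.ci_low if ps else np.nan,
                "ci_high": ps.ci_high if ps else np.nan,
                "wilcoxon_p": ps.wilcoxon_p if ps else np.nan,
                "n_agree": at.n_agree if at else 0,
                "n_disagree1": at.n_disagree1 if at else 0,
                "n_disagree2": at.n_disagree2 if at else 0,
                "chisq": chi.statistic if chi else np.nan,
                "chisq_p": chi.p if chi else np.nan,
            }
        )
    report["table"] = pd.DataFrame(rows)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(report["descriptives"]).T.to_csv(out_dir / "descriptives.csv")
        report["table"].to_csv(out_dir / "tables3_4.csv", index=False)
        (out_dir / "summary.txt").write_text(_render_summary(report))
    return report


def _render_summary(report: dict) -> str:
    lines = ["Paired JVP vs right-heart-catheterization comparison", ""]
    for m, desc in report["descriptives"].items():
        lines.append(
            f"{m:>12}: n={desc['n']:3d}  mean={desc['mean']:6.2f}  "
            f"sd={desc['sd']:5.2f}  IQR=({desc['iqr'][0]:.2f}, {desc['iqr'][1]:.2f}) cm H2O"
        )
    lines.append("")
    for m, ps in report["paired"].items():
        if isinstance(ps, str):
            lines.append(f"{m:>12}: {ps}")
            continue
        lines.append(
            f"{m:>12} vs RHC: mean diff {ps.mean_diff:+.2f} cm H2O "
            f"(95% CI {ps.ci_low:+.2f} to {ps.ci_high:+.2f}), "
            f"Wilcoxon p = {ps.wilcoxon_p:.4g}, n = {ps.n}"
        )
    lines.append("")
    for m, agr in report["agreement"].items():
        at, chi = agr["table"], agr["chisq"]
        if at is None:
            continue
        pct = at.percentages()
        lines.append(
            f"{m:>12}: agree {at.n_agree} ({pct['agree']['pct_int']}%), "
            f"disagree-by-1 {at.n_disagree1} ({pct['disagree1']['pct_int']}%), "
            f"disagree-by-2 {at.n_disagree2} ({pct['disagree2']['pct_int']}%); "
            f"chi2 = {chi.statistic:.3f}, p = {chi.p:.4g}"
        )
    return "\n".join(lines) + "\n"
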