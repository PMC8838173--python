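"""Match grading and agreement/reliability statistics for found segments.

Each found segment's tool label is graded against the reference label:

* **E** exact match — correct food type (or a synonym of it);
* **C** close match — correct food type but too generic, a slight variant,
  or with an overlooked ingredient (flags supplied by the analyst);
* **F** far match — wrong food type but correct food group;
* **M** mismatch — wrong type and wrong group.

Agreement at type/group/category granularity is summarised with the
Brennan–Prediger *uniform* kappa (chance probability fixed at 1/q, an
agreement index insensitive to marginal imbalance) alongside Cohen's kappa (a
reliability index), per-group sensitivity/specificity with exact
Clopper–Pearson intervals, and Fisher's exact test for proportion contrasts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.inter_rater import cohens_kappa as _sm_cohens_kappa

from .records import Segment
from .segmentation import proportion_halfwidth
from .taxonomy import FoodTaxonomy

__all__ = [
    "MatchGrade",
    "CLOSE_FLAGS",
    "grade_match",
    "classification_accuracy",
    "ConfusionTable",
    "confusion_table",
    "KappaResult",
    "cohen_kappa",
    "uniform_kappa",
    "uniform_kappa_ci",
    "SensSpecResult",
    "sensitivity_specificity",
    "fisher_exact",
]


class MatchGrade(str, Enum):
    E = "E"  # exact
    C = "C"  # close
    F = "F"  # far
    M = "M"  # mismatch


#: analyst flags that downgrade a same-type match from exact to close
CLOSE_FLAGS = frozenset({"too_generic", "slight_variant", "overlooked_ingredient"})


def grade_match(
    true_seg: Segment,
    app_seg: Segment,
    flags: Iterable[str] = (),
    tax: Optional[FoodTaxonomy] = None,
) -> MatchGrade:
    """Grade one found segment.

    Same food type -> E, unless an analyst close-flag (``too_generic``,
    ``slight_variant``, ``overlooked_ingredient``) applies -> C.  A
    ``synonym`` flag never downgrades (synonymous naming is still exact).
    Different type, same group -> F; different group -> M.  The taxonomy is
    required whenever the types differ.
    """
    flags = frozenset(flags)
    unknown = flags - CLOSE_FLAGS - {"synonym"}
    if unknown:
        raise ValueError(f"unknown grading flags {sorted(unknown)}")
    if true_seg.food_type == app_seg.food_type:
        return MatchGrade.C if flags & CLOSE_FLAGS else MatchGrade.E
    if tax is None:
        raise ValueError("taxonomy required to grade segments of different food types")
    if tax.group_of(true_seg.food_type) == tax.group_of(app_seg.food_type):
        return MatchGrade.F
    return MatchGrade.M


def classification_accuracy(
    grades: pd.DataFrame,
    by: Optional[str] = "record_type",
    include_total: bool = True,
) -> pd.DataFrame:
    """Proportions (+/- half-width) of E/C/F/M grades, per stratum.

    ``grades`` needs a ``grade`` column (values E/C/F/M) and, if ``by`` is
    given, that stratification column.  The four percentages sum to 100 in
    every stratum; half-widths use the n-1 normal-approximation convention.
    """
    if grades.empty:
        raise ValueError("no graded segments")
    frames = []
    groups: list[tuple[str, pd.DataFrame]] = []
    if by is not None:
        groups = [(str(k), g) for k, g in grades.groupby(by)]
    if include_total or by is None:
        groups.append(("total", grades))
    for stratum, g in groups:
        n = len(g)
        entry = {"stratum": stratum, "n": n}
        for grade in "ECFM":
            k = int((g["grade"] == grade).sum())
            entry[f"n_{grade}"] = k
            entry[f"pct_{grade}"] = 100.0 * k / n
            entry[f"hw_{grade}"] = proportion_halfwidth(k, n) if n >= 2 else float("nan")
        frames.append(entry)
    return pd.DataFrame(frames).set_index("stratum")


@dataclass(frozen=True)
class ConfusionTable:
    """Square label-by-label count matrix at one taxonomy level."""

    level: str  # type | group | category
    table: pd.DataFrame  # index = reference label, columns = tool label

    def __post_init__(self) -> None:
        if not self.table.index.equals(self.table.columns):
            raise ValueError("confusion table must be square over a shared label set")
        if (self.table.to_numpy() < 0).any():
            raise ValueError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return int(self.table.to_numpy().sum())

    def observed_agreement(self) -> float:
        return float(np.trace(self.table.to_numpy())) / self.n

    def binary_for(self, label: str) -> tuple[int, int, int, int]:
        """Collapse to one-vs-rest (TP, FN, FP, TN) for ``label``."""
        m = self.table.to_numpy()
        i = list(self.table.index).index(label)
        tp = int(m[i, i])
        fn = int(m[i, :].sum() - tp)
        fp = int(m[:, i].sum() - tp)
        tn = int(m.sum() - tp - fn - fp)
        return tp, fn, fp, tn


def confusion_table(
    pairs: Sequence[tuple[str, str]],
    level: str,
    tax: FoodTaxonomy,
    labels: Optional[Sequence[str]] = None,
) -> ConfusionTable:
    """Cross-tabulate (reference type, tool type) pairs at a taxonomy level.

    Labels are rolled up to ``level``; the label set defaults to every label
    the taxonomy defines at that level, so the matrix is square even when some
    labels never occur.
    """
    mapped = [
        (tax.level_label(ref_t, level), tax.level_label(app_t, level)) for ref_t, app_t in pairs
    ]
    if labels is None:
        if level == "type":
            labels = sorted(tax.types)
        elif level == "group":
            labels = sorted(tax.groups)
        else:
            labels = sorted(tax.categories)
    idx = pd.CategoricalIndex(labels, categories=labels)
    table = pd.DataFrame(0, index=idx, columns=idx)
    for ref_l, app_l in mapped:
        table.loc[ref_l, app_l] += 1
    table.index = pd.Index(labels, name="reference")
    table.columns = pd.Index(labels, name="tool")
    return ConfusionTable(level=level, table=table)


def cohen_kappa(conf: ConfusionTable | pd.DataFrame | np.ndarray) -> tuple[float, float]:
    """Cohen's kappa and its asymptotic standard error.

    kappa = (Po - Pe)/(1 - Pe) with Pe from the product of marginals; the SE
    is the standard asymptotic (Fleiss–Cohen–Everitt) one.  Degenerate tables
    with Pe = 1 (a single observed label on both sides) raise.
    """
    m = conf.table.to_numpy() if isinstance(conf, ConfusionTable) else np.asarray(conf)
    n = m.sum()
    if n < 2:
        raise ValueError("cohen_kappa needs at least two graded segments")
    p = m / n
    pe = float(p.sum(axis=0) @ p.sum(axis=1))
    if pe >= 1.0 - 1e-12:
        raise ValueError("degenerate confusion table: chance agreement is 1")
    res = _sm_cohens_kappa(m, return_results=True)
    return float(res.kappa), float(np.sqrt(res.var_kappa))


def uniform_kappa(po: float, q: int) -> float:
    """Brennan–Prediger uniform kappa: (q*Po - 1)/(q - 1).

    Chance agreement is fixed at 1/q (all q labels equally likely), so the
    index is an *agreement* measure unaffected by marginal prevalence; the
    binary case reduces to 2*Po - 1.
    """
    if q < 2:
        raise ValueError("uniform kappa needs q >= 2 categories")
    if not 0.0 <= po <= 1.0:
        raise ValueError("observed agreement must lie in [0, 1]")
    return (q * po - 1.0) / (q - 1.0)


def uniform_kappa_ci(
    indicators: Sequence[int] | np.ndarray,
    q: int,
    B: int = 2000,
    seed: int | np.random.Generator = 0,
    level: float = 0.95,
) -> tuple[float, float]:
    """Seeded percentile-bootstrap CI for the uniform kappa.

    ``indicators`` is the per-segment 0/1 agreement vector; each bootstrap
    replicate resamples segments with replacement and recomputes
    ``uniform_kappa(mean, q)``.
    """
    ind = np.asarray(indicators, dtype=float)
    if ind.size < 2:
        raise ValueError("bootstrap needs at least two segments")
    if B < 100:
        warnings.warn(f"B={B} bootstrap replicates is small; CI will be unstable")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    samples = rng.choice(ind, size=(B, ind.size), replace=True)
    kappas = (q * samples.mean(axis=1) - 1.0) / (q - 1.0)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(kappas, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


@dataclass(frozen=True)
class SensSpecResult:
    sensitivity: float  # percent; NaN when TP+FN == 0
    sens_ci: tuple[float, float]
    specificity: float  # percent; NaN when TN+FP == 0
    spec_ci: tuple[float, float]
    undefined: frozenset  # subset of {"sensitivity", "specificity"}


def _exact_ci_pct(x: int, n: int) -> tuple[float, float]:
    ci = stats.binomtest(x, n).proportion_ci(confidence_level=0.95, method="exact")
    return 100.0 * ci.low, 100.0 * ci.high


def sensitivity_specificity(tp: int, fn: int, fp: int, tn: int) -> SensSpecResult:
    """One-vs-rest sensitivity/specificity (percent) with exact 95% CIs.

    Clopper–Pearson intervals from the beta quantiles; an arm with a zero
    denominator is returned as NaN and named in ``undefined``.
    """
    if min(tp, fn, fp, tn) < 0:
        raise ValueError("cell counts must be non-negative")
    undefined = set()
    if tp + fn > 0:
        sens = 100.0 * tp / (tp + fn)
        sens_ci = _exact_ci_pct(tp, tp + fn)
    else:
        sens, sens_ci = float("nan"), (float("nan"), float("nan"))
        undefined.add("sensitivity")
    if tn + fp > 0:
        spec = 100.0 * tn / (tn + fp)
        spec_ci = _exact_ci_pct(tn, tn + fp)
    else:
        spec, spec_ci = float("nan"), (float("nan"), float("nan"))
        undefined.add("specificity")
    return SensSpecResult(sens, sens_ci, spec, spec_ci, frozenset(undefined))


def fisher_exact(table: Sequence[Sequence[int]] | np.ndarray) -> float:
    """Two-sided Fisher exact p for a 2x2 table (sum of tables as or less probable)."""
    m = np.asarray(table, dtype=int)
    if m.shape != (2, 2) or (m < 0).any():
        raise ValueError("fisher_exact needs a non-negative 2x2 table")
    if m.sum() < 1:
        raise ValueError("empty table")
    return float(stats.fisher_exact(m, alternative="two-sided")[1])


@dataclass(frozen=True)
class KappaResult:
    """Cohen and uniform kappa for one confusion table."""

    level: str
    q: int
    n: int
    cohen_kappa: float
    cohen_se: float
    uniform_kappa: float
    uniform_ci: tuple[float, float]

    def __post_init__(self) -> None:
        lo, hi = self.uniform_ci
        if not (lo - 1e-9 <= self.uniform_kappa <= hi + 1e-9):
            raise ValueError("uniform kappa must lie inside its CI")


def kappa_summary(
    conf: ConfusionTable,
    indicators: Sequence[int],
    B: int = 2000,
    seed: int | np.random.Generator = 0,
) -> KappaResult:
    """Bundle Cohen + uniform kappa (with bootstrap CI) for one level."""
    q = conf.table.shape[0]
    ck, se = cohen_kappa(conf)
    po = float(np.mean(indicators))
    ku = uniform_kappa(po, q)
    ci = uniform_kappa_ci(indicators, q, B=B, seed=seed)
    return KappaResult(
        level=conf.level, q=q, n=conf.n, cohen_kappa=ck, cohen_se=se,
        uniform_kappa=ku, uniform_ci=ci,
    )
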