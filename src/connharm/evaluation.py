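"""Two-criterion harmonization evaluation.

Criterion 1 — *site-effect removal*: the pooled two-site coefficient of
variation per graph measure, and a two-sided Mann-Whitney U test between the
sites' per-subject measure distributions (p > 0.05 after harmonization counts
as successful removal).

Criterion 2 — *biological-variability preservation*: Pearson correlation (and
ordinary least-squares fit) between age and each graph measure on the pooled
cohort (p < 0.05 counts as a significant, i.e. preserved, association).

Significance is starred at 0.05 / 0.005 / 0.001 with no multiple-testing
correction, matching the convention of the analysis this framework reports.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats

from connharm.io import SITES, CohortManifest
from connharm.measures import MEASURES


def significance_stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.005:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def coefficient_of_variation(values: Sequence[float]) -> float:
    """Sample SD (n-1 denominator) of the pooled values divided by their mean."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("coefficient of variation needs >= 2 values")
    mean = v.mean()
    if mean == 0:
        raise ValueError("coefficient of variation undefined for zero mean")
    return float(v.std(ddof=1) / mean)


def mann_whitney_u(group_a: Sequence[float], group_b: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann-Whitney U for group_a (rank-sum convention U_a).

    Normal approximation with midrank tie correction and continuity
    correction. Returns (U, p). U is reported for the first group as given
    (not min(U_a, U_b)), so values near 0 and near n_a*n_b are both possible.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("mann_whitney_u needs non-empty groups")
    with np.errstate(invalid="ignore"):
        res = scipy.stats.mannwhitneyu(
            a, b, alternative="two-sided", method="asymptotic", use_continuity=True
        )
    p = float(res.pvalue)
    if np.isnan(p):  # all observations tied: no evidence of a difference
        p = 1.0
    return float(res.statistic), min(p, 1.0)


def age_correlation(
    measure_values: Sequence[float], ages: Sequence[float]
) -> tuple[float, float, float, float]:
    """Pearson r between a measure and age, with OLS fit of measure on age.

    Returns (r, p, slope, intercept); p is two-sided from the exact t
    reference distribution with n - 2 degrees of freedom.
    """
    y = np.asarray(measure_values, dtype=float)
    x = np.asarray(ages, dtype=float)
    if x.size != y.size:
        raise ValueError("measure and age vectors differ in length")
    if x.size < 3:
        raise ValueError("age correlation needs n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("age correlation undefined for a constant vector")
    r, p = scipy.stats.pearsonr(x, y)
    fit = scipy.stats.linregress(x, y)
    return float(r), float(p), float(fit.slope), float(fit.intercept)


@dataclass
class EvaluationReport:
    """Per-(method, measure) evaluation table.

    Columns: method, measure, cov, u_stat, u_p, u_sig, r, r_p, r_sig, slope,
    intercept, site1_mean, site1_sd, site2_mean, site2_sd.
    """

    table: pd.DataFrame

    def write(self, out_dir: str | Path, prefix: str = "evaluation") -> dict[str, Path]:
        """Write the three report CSVs: age correlations, U tests, CoV."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        t = self.table
        paths = {}
        corr = t[["measure", "method", "r", "r_p", "r_sig", "slope", "intercept"]].rename(
            columns={"r": "statistic", "r_p": "p_value", "r_sig": "significance"}
        )
        paths["correlation"] = out_dir / f"{prefix}_age_correlation.csv"
        corr.to_csv(paths["correlation"], index=False)
        u = t[["measure", "method", "u_stat", "u_p", "u_sig"]].rename(
            columns={"u_stat": "statistic", "u_p": "p_value", "u_sig": "significance"}
        )
        paths["mann_whitney"] = out_dir / f"{prefix}_mann_whitney.csv"
        u.to_csv(paths["mann_whitney"], index=False)
        cov = t[["measure", "method", "cov", "site1_mean", "site1_sd", "site2_mean", "site2_sd"]]
        paths["cov"] = out_dir / f"{prefix}_cov.csv"
        cov.to_csv(paths["cov"], index=False)
        return paths


def evaluate_all(
    tables: Mapping[str, pd.DataFrame], manifest: CohortManifest
) -> EvaluationReport:
    """Evaluate each method's graph-measure table against both criteria.

    ``tables`` maps a method name (e.g. reference, shift_site1, shift_site2,
    combat) to a graph-measure table from :func:`connharm.measures.compute_all`.
    All tables must cover the same subjects as the manifest.
    """
    if not tables:
        raise ValueError("no method tables supplied")
    expected = set(manifest.subject_ids)
    ages = manifest.table.set_index("subject_id")["age"]
    sites = manifest.table.set_index("subject_id")["site"]
    rows = []
    for method, table in tables.items():
        got = set(table["subject_id"])
        if got != expected:
            raise ValueError(
                f"method {method!r} covers a different subject set "
                f"(missing {sorted(expected - got)[:3]}, extra {sorted(got - expected)[:3]})"
            )
        for measure in MEASURES:
            sub = table[table["measure"] == measure]
            vals = sub.set_index("subject_id")["value"]
            site_of = sites.loc[vals.index]
            v1 = vals[site_of == SITES[0]].to_numpy()
            v2 = vals[site_of == SITES[1]].to_numpy()
            u, u_p = mann_whitney_u(v1, v2)
            r, r_p, slope, intercept = age_correlation(
                vals.to_numpy(), ages.loc[vals.index].to_numpy()
            )
            rows.append(
                dict(
                    method=method,
                    measure=measure,
                    cov=coefficient_of_variation(vals.to_numpy()),
                    u_stat=u,
                    u_p=u_p,
                    u_sig=significance_stars(u_p),
                    r=r,
                    r_p=r_p,
                    r_sig=significance_stars(r_p),
                    slope=slope,
                    intercept=intercept,
                    site1_mean=float(v1.mean()),
                    site1_sd=float(v1.std(ddof=1)),
                    site2_mean=float(v2.mean()),
                    site2_sd=float(v2.std(ddof=1)),
                )
            )
    return EvaluationReport(pd.DataFrame(rows))
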