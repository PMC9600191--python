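"""Cohort-level statistics: burden, group comparisons, survival, co-mutation.

Test conventions, applied uniformly:

* Categorical variables — Pearson chi-squared *without* continuity
  correction when every expected cell count is >= 5, otherwise Fisher's
  exact test (2x2 only; larger tables always use chi-squared, with a note).
* Continuous variables — Wilcoxon rank-sum (Mann-Whitney U), two-sided.
* Survival — Kaplan-Meier per group with Greenwood confidence bands and
  log-rank tests; Cox proportional-hazards regression, univariate per
  covariate and multivariate over the covariates with univariate p < 0.05.
* Co-mutation enrichment — per gene pair, a 2x2 carrier-by-status table
  tested by Fisher's exact test; raw (uncorrected) p-values are reported.
"""

from __future__ import annotations

import logging
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .models import DataError, GIResult, PatientSampleSet

logger = logging.getLogger(__name__)

DEFAULT_COMUTATION_PAIRS = (
    ("TP53", "EGFR"),
    ("TP53", "RB1"),
    ("TP53", "ERBB2"),
    ("TP53", "KMT2C"),
)


# ---------------------------------------------------------------------------
# Categorical / continuous group tests

def categorical_test(table: np.ndarray | Sequence[Sequence[int]]) -> tuple[str, float]:
    """Chi-squared (no continuity correction) or Fisher's exact, by the
    expected-count rule.  Returns (test name, two-sided p)."""
    table = np.asarray(table, dtype=float)
    if table.sum() == 0:
        raise DataError("empty contingency table")
    expected = stats.contingency.expected_freq(table)
    if (expected >= 5).all():
        if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
            return "chi2", 1.0
        stat, p, _, _ = stats.chi2_contingency(table, correction=False)
        return "chi2", float(p)
    if table.shape == (2, 2):
        _, p = stats.fisher_exact(table, alternative="two-sided")
        return "fisher", float(p)
    logger.warning("low expected counts in %sx%s table; chi-squared used", *table.shape)
    stat, p, _, _ = stats.chi2_contingency(table, correction=False)
    return "chi2_low_counts", float(p)


def compare_groups(
    df: pd.DataFrame,
    group_var: str = "status",
    categorical: Sequence[str] = (),
    continuous: Sequence[str] = (),
) -> pd.DataFrame:
    """Per-variable two-group comparison table.

    Categorical variables report per-group ``n (%)`` per level and the
    chi-squared/Fisher p; continuous variables report ``median (IQR)`` and
    the Wilcoxon rank-sum p.  A variable constant across both groups is
    skipped with a note.
    """
    groups = [g for g in df[group_var].dropna().unique()]
    if len(groups) != 2:
        raise DataError(f"need exactly 2 groups in {group_var!r}, got {groups}")
    g1, g2 = sorted(groups, key=str)
    d1, d2 = df[df[group_var] == g1], df[df[group_var] == g2]
    rows = []
    for var in categorical:
        sub = df[[var, group_var]].dropna()
        levels = sorted(sub[var].unique(), key=str)
        if len(levels) < 2:
            rows.append(
                {"variable": var, "test": None, "p": None,
                 "note": "constant in both groups; skipped",
                 "summary": None}
            )
            continue
        table = np.array(
            [
                [int(((sub[var] == lv) & (sub[group_var] == g)).sum()) for g in (g1, g2)]
                for lv in levels
            ]
        )
        test, p = categorical_test(table)
        summary = {
            str(lv): {
                str(g): f"{table[i, j]} ({100 * table[i, j] / max(table[:, j].sum(), 1):.0f}%)"
                for j, g in enumerate((g1, g2))
            }
            for i, lv in enumerate(levels)
        }
        rows.append({"variable": var, "test": test, "p": p, "note": None,
                     "summary": summary})
    for var in continuous:
        x = d1[var].dropna().to_numpy(dtype=float)
        y = d2[var].dropna().to_numpy(dtype=float)
        if len(np.unique(np.concatenate([x, y]))) < 2:
            rows.append({"variable": var, "test": None, "p": None,
                         "note": "constant in both groups; skipped",
                         "summary": None})
            continue
        _, p = stats.mannwhitneyu(x, y, alternative="two-sided")
        summary = {
            str(g): f"{np.median(v):.3g} ({np.percentile(v, 25):.3g}, {np.percentile(v, 75):.3g})"
            for g, v in ((g1, x), (g2, y))
        }
        rows.append({"variable": var, "test": "wilcoxon_rank_sum", "p": float(p),
                     "note": None, "summary": summary})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Variant burden

def _somatic_counts(patient: PatientSampleSet, table) -> dict[str, int]:
    """Tumor-derived record counts: assay records absent from the leukocyte
    reference (germline hets shared with leukocytes are excluded)."""
    leuk_keys = patient.leukocyte.key_set()
    snv = sum(
        1 for r in table.records
        if r.kind in ("SNV", "indel") and r.key not in leuk_keys
    )
    cnv = sum(1 for r in table.records if r.kind == "CNV")
    return {"snv": snv, "cnv": cnv, "total": snv + cnv}


def variant_burden_summary(patients: Iterable[PatientSampleSet]) -> dict:
    """Paired CSF-vs-plasma burden comparison.

    Counts tumor-derived mutations (SNVs/indels plus CNV calls) per sample,
    compares paired totals by the Wilcoxon signed-rank test, and compares
    the any-CNV detection rate by the categorical-test rule.
    """
    rows = []
    for p in patients:
        if p.csf is None or p.plasma is None:
            continue
        csf = _somatic_counts(p, p.csf)
        pla = _somatic_counts(p, p.plasma)
        rows.append(
            {
                "patient_id": p.patient_id,
                "csf_total": csf["total"], "csf_snv": csf["snv"], "csf_cnv": csf["cnv"],
                "plasma_total": pla["total"], "plasma_snv": pla["snv"],
                "plasma_cnv": pla["cnv"],
            }
        )
    if len(rows) < 2:
        raise DataError("need >= 2 patients with paired CSF and plasma samples")
    burden = pd.DataFrame(rows)

    diffs = burden["csf_total"] - burden["plasma_total"]
    if (diffs == 0).all():
        wilcoxon_p = 1.0
    else:
        _, wilcoxon_p = stats.wilcoxon(
            burden["csf_total"], burden["plasma_total"], zero_method="wilcox"
        )
    csf_cnv_pos = int((burden["csf_cnv"] > 0).sum())
    pla_cnv_pos = int((burden["plasma_cnv"] > 0).sum())
    n = len(burden)
    cnv_table = [[csf_cnv_pos, n - csf_cnv_pos], [pla_cnv_pos, n - pla_cnv_pos]]
    if csf_cnv_pos == pla_cnv_pos:
        cnv_test, cnv_p = "none", 1.0
    else:
        cnv_test, cnv_p = categorical_test(cnv_table)
    return {
        "per_sample": burden,
        "wilcoxon_p": float(wilcoxon_p),
        "csf_mean_total": float(burden["csf_total"].mean()),
        "plasma_mean_total": float(burden["plasma_total"].mean()),
        "cnv_detection_rate": {"csf": csf_cnv_pos / n, "plasma": pla_cnv_pos / n},
        "cnv_rate_test": cnv_test,
        "cnv_rate_p": float(cnv_p),
    }


# ---------------------------------------------------------------------------
# Survival

def _encode_covariates(df: pd.DataFrame, covariates: Sequence[str]) -> pd.DataFrame:
    """Numeric design matrix; two-level strings become 0/1 indicators.

    Genomic status is encoded GS = 0 (reference), GI = 1; other binary
    variables use the alphabetically first level as reference.
    """
    out = pd.DataFrame(index=df.index)
    for cov in covariates:
        col = df[cov]
        if col.dtype == bool:
            out[cov] = col.astype(int)
        elif col.dtype == object or str(col.dtype) == "category":
            levels = sorted(col.dropna().unique(), key=str)
            if set(levels) == {"GI", "GS"}:
                out[cov] = (col == "GI").astype(int)
            elif len(levels) == 2:
                out[f"{cov}({levels[1]})"] = (col == levels[1]).astype(int)
            else:
                dummies = pd.get_dummies(col, prefix=cov, drop_first=True)
                out = pd.concat([out, dummies.astype(int)], axis=1)
        else:
            out[cov] = col.astype(float)
    return out


def survival_analysis(
    df: pd.DataFrame,
    endpoint: str,
    covariates: Sequence[str] = ("status",),
    group_var: str = "status",
    alpha_enter: float = 0.05,
) -> dict:
    """Kaplan-Meier + Cox analysis of one endpoint ("mfs" or "os").

    Expects columns ``{endpoint}_time`` and ``{endpoint}_event``.  Returns
    KM medians and curve coordinates per group, the log-rank p, and
    univariate plus multivariate Cox hazard ratios with 95% CIs (entry into
    the multivariate model requires univariate p < ``alpha_enter``).
    """
    from lifelines import CoxPHFitter, KaplanMeierFitter
    from lifelines.statistics import logrank_test

    time_col, event_col = f"{endpoint}_time", f"{endpoint}_event"
    for col in (time_col, event_col):
        if col not in df.columns:
            raise DataError(f"missing column {col!r} for endpoint {endpoint!r}")
    if (df[time_col] < 0).any():
        raise DataError("survival times must be >= 0")

    km: dict = {}
    groups = sorted(df[group_var].dropna().unique(), key=str)
    curves = []
    for g in groups:
        sub = df[df[group_var] == g]
        kmf = KaplanMeierFitter()
        kmf.fit(sub[time_col], sub[event_col], label=str(g))
        curve = kmf.survival_function_.copy()
        ci = kmf.confidence_interval_
        curve.columns = ["survival"]
        curve["ci_lower"] = ci.iloc[:, 0].to_numpy()
        curve["ci_upper"] = ci.iloc[:, 1].to_numpy()
        curve["group"] = str(g)
        curves.append(curve.reset_index(names="time"))
        km[str(g)] = {
            "n": int(len(sub)),
            "events": int(sub[event_col].sum()),
            "median": float(kmf.median_survival_time_),
        }
    logrank_p = None
    if len(groups) == 2:
        a = df[df[group_var] == groups[0]]
        b = df[df[group_var] == groups[1]]
        if a[event_col].sum() > 0 or b[event_col].sum() > 0:
            res = logrank_test(
                a[time_col], b[time_col], a[event_col], b[event_col]
            )
            logrank_p = float(res.p_value)

    design = _encode_covariates(df, covariates)
    uni_rows = []
    for col in design.columns:
        data = pd.concat([df[[time_col, event_col]], design[[col]]], axis=1).dropna()
        unstable = False
        # separation guard: a binary covariate with an event-free level
        if set(data[col].unique()) <= {0, 1}:
            for level in (0, 1):
                sub = data[data[col] == level]
                if len(sub) and sub[event_col].sum() == 0:
                    unstable = True
        try:
            cph = CoxPHFitter()
            cph.fit(data, duration_col=time_col, event_col=event_col)
            s = cph.summary.loc[col]
            uni_rows.append(
                {
                    "covariate": col,
                    "hr": float(s["exp(coef)"]),
                    "ci_lower": float(s["exp(coef) lower 95%"]),
                    "ci_upper": float(s["exp(coef) upper 95%"]),
                    "p": float(s["p"]),
                    "unstable": unstable,
                }
            )
        except Exception as exc:
            uni_rows.append(
                {"covariate": col, "hr": None, "ci_lower": None, "ci_upper": None,
                 "p": None, "unstable": True}
            )
            logger.warning("univariate Cox failed for %s: %s", col, exc)
    univariate = pd.DataFrame(uni_rows)

    selected = [
        r["covariate"]
        for r in uni_rows
        if r["p"] is not None and r["p"] < alpha_enter and not r["unstable"]
    ]
    if selected:
        data = pd.concat([df[[time_col, event_col]], design[selected]], axis=1).dropna()
        cph = CoxPHFitter()
        cph.fit(data, duration_col=time_col, event_col=event_col)
        multi_rows = [
            {
                "covariate": cov,
                "hr": float(cph.summary.loc[cov, "exp(coef)"]),
                "ci_lower": float(cph.summary.loc[cov, "exp(coef) lower 95%"]),
                "ci_upper": float(cph.summary.loc[cov, "exp(coef) upper 95%"]),
                "p": float(cph.summary.loc[cov, "p"]),
            }
            for cov in selected
        ]
        multivariate = pd.DataFrame(multi_rows)
    else:
        multivariate = pd.DataFrame(
            columns=["covariate", "hr", "ci_lower", "ci_upper", "p"]
        )

    return {
        "endpoint": endpoint,
        "km": km,
        "km_curves": pd.concat(curves, ignore_index=True) if curves else pd.DataFrame(),
        "logrank_p": logrank_p,
        "univariate": univariate,
        "multivariate": multivariate,
    }


# ---------------------------------------------------------------------------
# Co-mutation enrichment

def gene_mutation_matrix(
    patients: Iterable[PatientSampleSet],
    genes: Optional[Sequence[str]] = None,
    compartment: str = "csf",
    include_cnv: bool = False,
) -> pd.DataFrame:
    """Patient-by-gene boolean indicator of tumor-derived mutation.

    A gene counts as mutated when the compartment table carries a
    SNV/indel record for it that is absent from the leukocyte reference
    (CNV records optionally included via ``include_cnv``).
    """
    rows = {}
    all_genes: set[str] = set(genes) if genes else set()
    for p in patients:
        table = getattr(p, compartment)
        if table is None:
            continue
        leuk_keys = p.leukocyte.key_set()
        mutated = set()
        for r in table.records:
            if r.gene is None or r.key in leuk_keys:
                continue
            if r.kind in ("SNV", "indel") or (include_cnv and r.kind == "CNV"):
                mutated.add(r.gene)
        rows[p.patient_id] = mutated
        if genes is None:
            all_genes |= mutated
    genes_sorted = sorted(all_genes)
    return pd.DataFrame(
        {g: [g in rows[pid] for pid in rows] for g in genes_sorted},
        index=list(rows),
    )


def comutation_enrichment(
    mutations: pd.DataFrame,
    status: pd.Series,
    gene_pairs: Sequence[tuple[str, str]] = DEFAULT_COMUTATION_PAIRS,
    scores: Optional[pd.Series] = None,
) -> pd.DataFrame:
    """Per-pair co-mutation enrichment between GI and GS patients.

    For each gene pair, carriers (both genes mutated) are cross-tabulated
    against genomic status and tested by Fisher's exact test; when a score
    series is supplied, carrier vs non-carrier scores are compared by the
    Wilcoxon rank-sum test.
    """
    status = status.loc[mutations.index]
    gi_mask = (status == "GI").to_numpy()
    rows = []
    for g1, g2 in gene_pairs:
        if g1 not in mutations.columns or g2 not in mutations.columns:
            rows.append({"pair": f"{g1}/{g2}", "note": "gene absent",
                         "freq_gi": None, "freq_gs": None,
                         "odds_ratio": None, "p": None, "score_p": None})
            continue
        carrier = (mutations[g1] & mutations[g2]).to_numpy()
        n_gi, n_gs = int(gi_mask.sum()), int((~gi_mask).sum())
        a = int((carrier & gi_mask).sum())
        b = int((carrier & ~gi_mask).sum())
        if carrier.sum() == 0:
            rows.append({"pair": f"{g1}/{g2}", "note": "no carriers",
                         "freq_gi": 0.0, "freq_gs": 0.0,
                         "odds_ratio": None, "p": 1.0, "score_p": None})
            continue
        table = [[a, n_gi - a], [b, n_gs - b]]
        odds, p = stats.fisher_exact(table, alternative="two-sided")
        score_p = None
        if scores is not None:
            s = scores.loc[mutations.index].to_numpy(dtype=float)
            ok = np.isfinite(s)
            if carrier[ok].any() and (~carrier[ok]).any():
                _, score_p = stats.mannwhitneyu(
                    s[ok & carrier], s[ok & ~carrier], alternative="two-sided"
                )
                score_p = float(score_p)
        rows.append(
            {
                "pair": f"{g1}/{g2}",
                "note": None,
                "freq_gi": a / n_gi if n_gi else None,
                "freq_gs": b / n_gs if n_gs else None,
                "odds_ratio": float(odds) if np.isfinite(odds) else None,
                "p": float(p),
                "score_p": score_p,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Correlation

def correlate(
    x: Sequence[float], y: Sequence[float], method: str = "pearson"
) -> tuple[float, float]:
    """Correlation coefficient and two-sided p for paired vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise DataError("correlation needs paired vectors of length >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise DataError("correlation inputs must be finite")
    if np.std(x) == 0 or np.std(y) == 0:
        raise DataError("zero variance in correlation input")
    if method == "pearson":
        r, p = stats.pearsonr(x, y)
    elif method == "spearman":
        r, p = stats.spearmanr(x, y)
    else:
        raise DataError(f"unknown correlation method {method!r}")
    return float(r), float(p)


def gi_results_by_compartment(
    results: Iterable[GIResult], compartment: str
) -> pd.Series:
    """Scores of one compartment indexed by patient, for merging with
    clinical frames."""
    return pd.Series(
        {
            r.patient_id: r.score
            for r in results
            if r.compartment == compartment and r.score is not None
        }
    )
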