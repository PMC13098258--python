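"""Species- and genome-unit-level disease association testing.

The species layer regresses centered log-ratio (CLR) transformed relative
abundances on a binary disease indicator adjusted for BMI, sex and age
(ordinary least squares, Wald test on the disease coefficient). The
within-species layer fits logistic regressions of disease status on genome
unit presence/absence with the same covariates and reports odds ratios.
Multiple testing is controlled by Bonferroni: the species layer divides the
nominal alpha by the number of species tested, the unit layer by the number
of diseases.

Compositional zeros are replaced, before the CLR, by half of the smallest
nonzero relative abundance in the whole table (rows renormalized afterwards);
the rule is configurable via ``pseudocount``.

Degenerate designs (constant disease indicator, unit present or absent in
every sample, perfect separation) are returned as flagged results with
``status`` != "ok" and NaN statistics — never silently dropped and never a
crash.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.tools.sm_exceptions import PerfectSeparationError

COVARIATES = ("bmi", "sex", "age")


@dataclass
class AssociationResult:
    """One (feature, disease) test from either MWAS layer."""

    level: str  # "species" | "unit"
    feature_id: str
    disease_id: str
    n_cases: int
    n_controls: int
    effect: float  # beta1 (linear) or log-OR (logistic)
    se: float
    p_value: float
    odds_ratio: float | None
    alpha_corrected: float
    significant: bool
    status: str = "ok"  # ok | degenerate | separation | nonconverged


def clr_transform(
    abundance: pd.DataFrame, pseudocount: str | float = "half-min"
) -> pd.DataFrame:
    """Centered log-ratio transform of a samples × species abundance table.

    Zeros are replaced per ``pseudocount``: "half-min" (default) uses half of
    the table-wide smallest nonzero value; a float is used verbatim. Rows are
    renormalized after replacement, so each output row sums to 0.
    """
    x = abundance.to_numpy(dtype=float)
    if (x < 0).any():
        raise ValueError("abundances must be non-negative")
    zero_rows = ~(x > 0).any(axis=1)
    if zero_rows.any():
        bad = abundance.index[zero_rows][0]
        raise ValueError(f"sample {bad!r} has an all-zero composition")
    if pseudocount == "half-min":
        repl = 0.5 * x[x > 0].min()
    else:
        repl = float(pseudocount)
    x = np.where(x > 0, x, repl)
    x = x / x.sum(axis=1, keepdims=True)
    logx = np.log(x)
    y = logx - logx.mean(axis=1, keepdims=True)
    return pd.DataFrame(y, index=abundance.index, columns=abundance.columns)


def filter_species(abundance: pd.DataFrame, min_prevalence: float = 0.01) -> list[str]:
    """Species detected (nonzero) in at least ``min_prevalence`` of samples (inclusive)."""
    prev = (abundance > 0).mean(axis=0)
    return [s for s in abundance.columns if prev[s] >= min_prevalence]


def filter_diseases(
    phenotypes: pd.DataFrame, diseases: Sequence[str], min_cases: int = 100
) -> list[str]:
    """Diseases with at least ``min_cases`` cases; remaining samples are controls."""
    return [d for d in diseases if int(phenotypes[d].sum()) >= min_cases]


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Bonferroni-corrected per-test alpha."""
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha {alpha} outside (0, 1)")
    if m < 1:
        raise ValueError("number of tests must be at least 1")
    return alpha / m


def _flagged(level, feature, disease, n_cases, n_controls, alpha_c, status):
    return AssociationResult(
        level, feature, disease, n_cases, n_controls,
        float("nan"), float("nan"), float("nan"),
        None if level == "species" else float("nan"),
        alpha_c, False, status,
    )


def species_mwas(
    clr: pd.DataFrame,
    phenotypes: pd.DataFrame,
    diseases: Sequence[str],
    covariates: Sequence[str] = COVARIATES,
    alpha: float = 0.05,
) -> list[AssociationResult]:
    """Linear MWAS: CLR abundance ~ disease + BMI + sex + age, per (species, disease).

    Bonferroni divisor = number of species tested.
    """
    missing = clr.index.difference(phenotypes.index)
    if len(missing):
        raise ValueError(f"samples missing from phenotypes: {list(missing)[:3]}")
    pheno = phenotypes.loc[clr.index]
    if pheno[list(covariates)].isna().any().any():
        raise ValueError("missing covariate values for analyzed samples")
    alpha_c = bonferroni_threshold(alpha, len(clr.columns))
    cov = pheno[list(covariates)].to_numpy(dtype=float)
    results = []
    for disease in diseases:
        d = pheno[disease].to_numpy(dtype=float)
        n_cases = int(d.sum())
        n_controls = len(d) - n_cases
        degenerate = d.min() == d.max()
        X = sm.add_constant(np.column_stack([d, cov]), has_constant="add")
        for species in clr.columns:
            if degenerate:
                results.append(
                    _flagged("species", species, disease, n_cases, n_controls,
                             alpha_c, "degenerate")
                )
                continue
            fit = sm.OLS(clr[species].to_numpy(), X).fit()
            beta, se, p = fit.params[1], fit.bse[1], fit.pvalues[1]
            results.append(
                AssociationResult(
                    "species", species, disease, n_cases, n_controls,
                    float(beta), float(se), float(p), None, alpha_c,
                    bool(p < alpha_c), "ok",
                )
            )
    return results


def unit_presence_matrix(
    recovery: pd.DataFrame,
    unit_of_mag: Mapping[str, str],
    samples: Sequence[str],
    units: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Binary samples × units matrix: 1 iff a MAG of that unit came from that sample.

    ``recovery`` needs columns sample_id and mag_id; ``unit_of_mag`` maps
    mag_id → genome unit id (MAGs outside the mapping are ignored).
    """
    if units is None:
        units = sorted(set(unit_of_mag.values()))
    mat = pd.DataFrame(0, index=list(samples), columns=list(units), dtype=int)
    for r in recovery.itertuples():
        unit = unit_of_mag.get(str(r.mag_id))
        if unit is not None and unit in mat.columns:
            mat.loc[str(r.sample_id), unit] = 1
    return mat


def within_species_mwas(
    presence: pd.DataFrame,
    phenotypes: pd.DataFrame,
    diseases: Sequence[str],
    covariates: Sequence[str] = ("sex", "age", "bmi"),
    min_carriers: int = 100,
    alpha: float = 0.05,
) -> list[AssociationResult]:
    """Logistic MWAS: disease ~ unit presence + sex + age + BMI, per (unit, disease).

    Units carried by fewer than ``min_carriers`` samples are skipped before
    testing. Bonferroni divisor = number of diseases. OR = exp(beta1).
    """
    pheno = phenotypes.loc[presence.index]
    alpha_c = bonferroni_threshold(alpha, len(diseases))
    cov = pheno[list(covariates)].to_numpy(dtype=float)
    kept_units = [u for u in presence.columns if int(presence[u].sum()) >= min_carriers]
    results = []
    for unit in kept_units:
        carrier = presence[unit].to_numpy(dtype=float)
        unit_degenerate = carrier.min() == carrier.max()
        X = sm.add_constant(np.column_stack([carrier, cov]), has_constant="add")
        for disease in diseases:
            d = pheno[disease].to_numpy(dtype=float)
            n_cases = int(d.sum())
            n_controls = len(d) - n_cases
            if unit_degenerate or d.min() == d.max():
                results.append(
                    _flagged("unit", unit, disease, n_cases, n_controls,
                             alpha_c, "degenerate")
                )
                continue
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    fit = sm.Logit(d, X).fit(disp=0, maxiter=100)
                converged = bool(fit.mle_retvals.get("converged", False))
            except (np.linalg.LinAlgError, PerfectSeparationError):
                results.append(
                    _flagged("unit", unit, disease, n_cases, n_controls,
                             alpha_c, "separation")
                )
                continue
            beta, se, p = fit.params[1], fit.bse[1], fit.pvalues[1]
            if not converged or not np.isfinite(se) or se > 1e3:
                results.append(
                    _flagged("unit", unit, disease, n_cases, n_controls,
                             alpha_c, "separation" if se > 1e3 else "nonconverged")
                )
                continue
            results.append(
                AssociationResult(
                    "unit", unit, disease, n_cases, n_controls,
                    float(beta), float(se), float(p), float(np.exp(beta)),
                    alpha_c, bool(p < alpha_c), "ok",
                )
            )
    return results


def results_to_table(results: Sequence[AssociationResult]) -> pd.DataFrame:
    """Flat results table matching the documented TSV layout."""
    return pd.DataFrame(
        [
            {
                "level": r.level,
                "feature_id": r.feature_id,
                "disease_id": r.disease_id,
                "n_cases": r.n_cases,
                "n_controls": r.n_controls,
                "effect": r.effect,
                "se": r.se,
                "p_value": r.p_value,
                "or": "" if r.odds_ratio is None else r.odds_ratio,
                "alpha_corrected": r.alpha_corrected,
                "significant": int(r.significant),
                "status": r.status,
            }
            for r in results
        ]
    )


def accumulation_curve(
    novel_by_sample: Mapping[str, set[str]],
    n_permutations: int = 20,
    seed: int = 0,
) -> tuple[np.ndarray, float, float]:
    """Novel-species accumulation over random sample orderings.

    Returns (mean cumulative curve of length n_samples, least-squares slope
    expressed per 500 samples, R² of the linear fit to the mean curve).
    """
    if n_permutations < 1:
        raise ValueError("need at least one permutation")
    samples = sorted(novel_by_sample)
    n = len(samples)
    rng = np.random.default_rng(seed)
    curves = np.zeros((n_permutations, n))
    for p in range(n_permutations):
        order = rng.permutation(n)
        seen: set[str] = set()
        for i, idx in enumerate(order):
            seen |= novel_by_sample[samples[idx]]
            curves[p, i] = len(seen)
    mean_curve = curves.mean(axis=0)
    xs = np.arange(1, n + 1, dtype=float)
    slope, intercept, r, _, _ = stats.linregress(xs, mean_curve)
    if np.ptp(mean_curve) == 0:  # flat curve: no novel species anywhere
        slope, r = 0.0, 1.0
    return mean_curve, float(slope * 500.0), float(r**2)
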