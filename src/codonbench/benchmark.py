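"""Model-comparison protocol: random-model ensembles, LRT, BIC, tables.

The central exercise: fit the single-rate (SR) model once, then fit many
multi-rate models whose rate classes were assigned *at random*, and ask
how often the random models significantly beat SR.  Because SR is nested
in every K-class model, each comparison is a likelihood-ratio test with
df equal to the difference in estimable rate parameters; a Bonferroni
correction over the replicate count gives the conservative paired count.
Model ranking across families uses BIC with n = codon sites.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .inference import (
    CodonAlignment,
    FitOptions,
    FitResult,
    PhyloTree,
    fit,
    warm_start_options,
)
from .ratematrix import RateClassAssignment, random_assignment, sr_assignment

LR_TOLERANCE = 1e-6  # nested optima may differ by optimizer noise


@dataclass
class ModelComparison:
    """A likelihood-ratio test between nested fits."""

    lr_statistic: float
    df: int
    p_value: float
    alpha: float
    alpha_bonferroni: float
    significant_raw: bool
    significant_bonferroni: bool


def _is_nested(null_fit: FitResult, alt_fit: FitResult) -> bool:
    null_a: RateClassAssignment = null_fit.assignment
    alt_a: RateClassAssignment = alt_fit.assignment
    if null_a.n_effective_classes == 1:
        return set(null_a.class_of) == set(alt_a.class_of)
    return alt_a.refines(null_a)


def lrt(
    null_fit: FitResult,
    alt_fit: FitResult,
    alpha: float = 0.05,
    n_tests: int = 1,
) -> ModelComparison:
    """Likelihood-ratio test of a nested null against a richer alternative.

    The statistic is 2(LL_alt - LL_null), compared to a chi-square with
    df equal to the difference in free-parameter counts.  Slightly
    negative statistics (within optimizer tolerance) are clamped to 0;
    larger negative values indicate a broken fit and raise.
    """
    if not _is_nested(null_fit, alt_fit):
        raise ValueError(
            f"models are not nested: {null_fit.model_descriptor['label']} vs "
            f"{alt_fit.model_descriptor['label']}"
        )
    stat = 2.0 * (alt_fit.log_likelihood - null_fit.log_likelihood)
    if stat < -LR_TOLERANCE * max(1.0, abs(null_fit.log_likelihood)):
        raise ValueError(
            f"alternative fit has lower likelihood than nested null "
            f"(LR statistic {stat:.6g}); refit before testing"
        )
    stat = max(stat, 0.0)
    df = alt_fit.n_free_parameters - null_fit.n_free_parameters
    if df < 1:
        raise ValueError(f"LRT requires df >= 1, got {df}")
    p = float(chi2.sf(stat, df))
    alpha_b = alpha / n_tests
    return ModelComparison(
        lr_statistic=stat,
        df=df,
        p_value=p,
        alpha=alpha,
        alpha_bonferroni=alpha_b,
        significant_raw=p < alpha,
        significant_bonferroni=p < alpha_b,
    )


def bic(fit_result: FitResult, n: int) -> float:
    """Bayesian information criterion, -2*LL + p*ln(n); smaller is better."""
    if n < 1:
        raise ValueError(f"sample size must be >= 1, got {n}")
    return -2.0 * fit_result.log_likelihood + fit_result.n_free_parameters * np.log(n)


@dataclass
class EnsembleResult:
    """Outcome of a random-model ensemble against the SR fit."""

    K: int
    n_replicates: int
    seeds: list[int]
    sr_fit: FitResult
    fits: list[FitResult]
    comparisons: list[ModelComparison | None]
    n_significant_raw: int
    n_significant_bonferroni: int
    n_nonconverged: int
    mean_bic: float
    sr_bic: float
    alpha: float

    @property
    def rejection_fraction(self) -> float:
        usable = self.n_replicates - self.n_nonconverged
        return self.n_significant_raw / usable if usable else float("nan")


def run_random_ensemble(
    aln: CodonAlignment,
    tree: PhyloTree,
    K: int,
    n_replicates: int = 100,
    base_seed: int = 1,
    alpha: float = 0.05,
    options: FitOptions | None = None,
    sr_fit: FitResult | None = None,
) -> EnsembleResult:
    """Fit SR once, then ``n_replicates`` random K-class models.

    Replicate r uses the assignment drawn with seed ``base_seed + r``
    and is warm-started from the SR optimum (which preserves likelihood
    nesting), then fully re-optimized with the same settings.  Tests are
    reported both at ``alpha`` and at the Bonferroni-corrected
    ``alpha / n_replicates``; non-converged replicates are tallied and
    excluded from the significance counts and the mean BIC.
    """
    options = options or FitOptions()
    if sr_fit is None:
        sr_fit = fit(tree, aln, sr_assignment(), options)
    n = aln.n_sites
    sr_bic = bic(sr_fit, n)

    seeds = [base_seed + r for r in range(n_replicates)]
    fits: list[FitResult] = []
    comparisons: list[ModelComparison | None] = []
    n_raw = n_bonf = n_bad = 0
    bics: list[float] = []
    for seed in seeds:
        assignment = random_assignment(K, seed=seed)
        opts = warm_start_options(options, sr_fit, assignment.n_classes)
        res = fit(tree, aln, assignment, opts)
        fits.append(res)
        if not res.converged:
            n_bad += 1
            comparisons.append(None)
            continue
        cmp_ = lrt(sr_fit, res, alpha=alpha, n_tests=n_replicates)
        comparisons.append(cmp_)
        n_raw += cmp_.significant_raw
        n_bonf += cmp_.significant_bonferroni
        bics.append(bic(res, n))

    return EnsembleResult(
        K=K,
        n_replicates=n_replicates,
        seeds=seeds,
        sr_fit=sr_fit,
        fits=fits,
        comparisons=comparisons,
        n_significant_raw=n_raw,
        n_significant_bonferroni=n_bonf,
        n_nonconverged=n_bad,
        mean_bic=float(np.mean(bics)) if bics else float("nan"),
        sr_bic=sr_bic,
        alpha=alpha,
    )


@dataclass
class AlignmentBenchmark:
    """All benchmark artefacts for one alignment, ready for table layout."""

    label: str
    n_taxa: int
    n_sites: int
    ensembles: dict[int, EnsembleResult] = field(default_factory=dict)
    model_fits: dict[str, FitResult] = field(default_factory=dict)


def summarize(
    records: list[AlignmentBenchmark],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Render benchmark tables.

    Returns a significance table (one row per alignment; per-K counts of
    random models beating SR, Bonferroni counts in parentheses) and a
    BIC table (named model fits plus the ensemble mean BIC per K, with
    the per-alignment minimum starred).
    """
    ks = sorted({k for r in records for k in r.ensembles})
    model_names = sorted({m for r in records for m in r.model_fits})

    sig_rows = []
    for r in records:
        row: dict[str, object] = {
            "alignment": r.label,
            "taxa": r.n_taxa,
            "sites": r.n_sites,
        }
        for k in ks:
            ens = r.ensembles.get(k)
            row[f"K={k}"] = (
                f"{ens.n_significant_raw} ({ens.n_significant_bonferroni})"
                if ens is not None
                else ""
            )
        sig_rows.append(row)
    sig_cols = ["alignment", "taxa", "sites"] + [f"K={k}" for k in ks]
    sig = pd.DataFrame(sig_rows, columns=sig_cols)

    bic_rows = []
    for r in records:
        values: dict[str, float] = {}
        for name in model_names:
            if name in r.model_fits:
                values[name] = bic(r.model_fits[name], r.n_sites)
        for k in ks:
            if k in r.ensembles:
                values[f"random-K{k}"] = r.ensembles[k].mean_bic
        best = min(values, key=values.get) if values else None
        row = {"alignment": r.label}
        for name, v in values.items():
            row[name] = f"{v:.1f}*" if name == best else f"{v:.1f}"
        bic_rows.append(row)
    bic_cols = ["alignment"] + model_names + [f"random-K{k}" for k in ks]
    bic_table = pd.DataFrame(bic_rows, columns=bic_cols)
    return sig, bic_table
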