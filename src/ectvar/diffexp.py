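"""One-case-versus-N-controls differential expression on novel EC counts.

The model is a negative-binomial GLM with log link, log-library-size
offset and a *fixed* dispersion (default 0.1, not estimated). The
alternative fits separate mean rates for the case "group" (one sample) and
the control group; the null fits a single shared rate. Significance comes
from the likelihood-ratio statistic against chi-square with 1 df, with
Benjamini-Hochberg control of the FDR across ECs. An EC is significant
when FDR < ``fdr_max`` and logFC > ``logfc_min`` (both strict), where the
log2 fold change uses a small prior count on both groups to avoid
infinities.

When no controls are available, testing is skipped and ECs are selected on
the case-CPM filter alone.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Set, Tuple

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .quant import MatchedECMatrix


@dataclass
class DEParams:
    """Testing and filtering parameters.

    ``dispersion`` is the NB overdispersion phi in Var = mu + phi*mu^2.
    ``logfc_min`` defaults to 2; large-cohort screens typically raise it
    to 5 to suppress background variation.
    """

    dispersion: float = 0.1
    cpm_min: float = 0.1
    fdr_max: float = 0.05
    logfc_min: float = 2.0
    prior_count: float = 0.5

    def __post_init__(self) -> None:
        if min(self.dispersion, self.cpm_min, self.fdr_max, self.logfc_min,
               self.prior_count) <= 0 or self.fdr_max > 1:
            raise ValueError("DE parameters must be positive with fdr_max in (0, 1]")


@dataclass
class DEResult:
    ec: Tuple[str, ...]
    case_count: int
    control_counts: Tuple[int, ...]
    case_cpm: float
    logfc: float
    lrt_stat: float
    p_value: float
    fdr: float = float("nan")
    significant: bool = False


def cpm(count: float, library_size: float) -> float:
    """Counts per million mapped read ends."""
    if library_size <= 0:
        raise ValueError("library_size must be positive")
    return count * 1e6 / library_size


def filter_low_expression(matrix: MatchedECMatrix, params: DEParams) -> MatchedECMatrix:
    """Keep ECs with case CPM strictly above ``cpm_min``. Library sizes are
    untouched."""
    lib = matrix.library_sizes[matrix.case_index]
    case = matrix.matrix[:, matrix.case_index]
    keep = [i for i in range(matrix.n_ecs) if cpm(case[i], lib) > params.cpm_min]
    return MatchedECMatrix(
        ec_list=[matrix.ec_list[i] for i in keep],
        matrix=matrix.matrix[keep, :] if keep else np.zeros((0, len(matrix.sample_ids)), dtype=np.int64),
        sample_ids=list(matrix.sample_ids),
        library_sizes=matrix.library_sizes.copy(),
        case_index=matrix.case_index,
    )


# -- NB likelihood machinery ----------------------------------------------


def _nb_loglik(y: np.ndarray, mu: np.ndarray, phi: float) -> float:
    """Negative-binomial log likelihood at fixed dispersion."""
    n = 1.0 / phi
    mu = np.maximum(mu, 1e-12)
    p = n / (n + mu)
    return float(stats.nbinom.logpmf(y, n, p).sum())


def fit_nb_rate(y: np.ndarray, lib: np.ndarray, phi: float) -> float:
    """Maximum-likelihood common rate r for counts y_i ~ NB(r * lib_i, phi).

    Newton iteration on theta = log r; the log likelihood is concave in
    theta. With equal library sizes the optimum is the closed form
    sum(y)/sum(lib), which is also the starting point.
    """
    total = y.sum()
    if total == 0:
        return 0.0
    theta = np.log(total / lib.sum())
    inv_phi = 1.0 / phi
    for _ in range(50):
        mu = np.exp(theta) * lib
        w = phi * mu / (1.0 + phi * mu)
        grad = float((y - (y + inv_phi) * w).sum())
        hess = float((-(y + inv_phi) * w / (1.0 + phi * mu)).sum())
        if hess == 0:
            break
        step = -grad / hess
        step = max(min(step, 5.0), -5.0)
        theta += step
        if abs(step) < 1e-12:
            break
    return float(np.exp(theta))


def nb_lrt_test(
    ec_counts: Sequence[int],
    library_sizes: Sequence[float],
    case_index: int,
    params: DEParams,
) -> Tuple[float, float, float]:
    """Fixed-dispersion NB likelihood-ratio test of case rate vs control rate.

    Returns (logFC, lrt_stat, p_value). The LRT statistic is floored at 0
    and referred to chi-square(1); logFC is the prior-stabilised log2 ratio
    of case to pooled-control rates.
    """
    y = np.asarray(ec_counts, dtype=float)
    lib = np.asarray(library_sizes, dtype=float)
    if not (np.isfinite(y).all() and np.isfinite(lib).all()):
        raise ValueError("non-finite counts or library sizes")
    if y.min() < 0 or lib.min() <= 0:
        raise ValueError("counts must be non-negative and libraries positive")
    ctrl = np.ones(len(y), dtype=bool)
    ctrl[case_index] = False
    if not ctrl.any():
        raise ValueError("at least one control is required")
    phi = params.dispersion

    y_case, lib_case = y[~ctrl], lib[~ctrl]
    y_ctrl, lib_ctrl = y[ctrl], lib[ctrl]

    logfc = float(
        np.log2((y_case.sum() + params.prior_count) / lib_case.sum())
        - np.log2((y_ctrl.sum() + params.prior_count) / lib_ctrl.sum())
    )
    if y.sum() == 0:
        return 0.0, 0.0, 1.0

    r_case = float(y_case.sum() / lib_case.sum())  # single observation: exact MLE
    r_ctrl = fit_nb_rate(y_ctrl, lib_ctrl, phi)
    r_null = fit_nb_rate(y, lib, phi)
    ll_alt = _nb_loglik(y_case, r_case * lib_case, phi) + _nb_loglik(
        y_ctrl, r_ctrl * lib_ctrl, phi
    )
    ll_null = _nb_loglik(y, r_null * lib, phi)
    lrt = max(0.0, 2.0 * (ll_alt - ll_null))
    p = float(stats.chi2.sf(lrt, df=1))
    return logfc, lrt, p


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order preserving)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if p.min() < 0 or p.max() > 1:
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def run_de(matrix: MatchedECMatrix, params: DEParams) -> List[DEResult]:
    """Test every EC of a (novel, CPM-filtered) matrix; fills FDR and the
    significance flag (FDR < fdr_max and logFC > logfc_min, both strict)."""
    lib = matrix.library_sizes.astype(float)
    case_lib = lib[matrix.case_index]
    results: List[DEResult] = []
    for i, ec in enumerate(matrix.ec_list):
        row = matrix.matrix[i, :]
        logfc, lrt, p = nb_lrt_test(row, lib, matrix.case_index, params)
        ctrl = [int(c) for j, c in enumerate(row) if j != matrix.case_index]
        results.append(
            DEResult(
                ec=ec,
                case_count=int(row[matrix.case_index]),
                control_counts=tuple(ctrl),
                case_cpm=cpm(row[matrix.case_index], case_lib),
                logfc=logfc,
                lrt_stat=lrt,
                p_value=p,
            )
        )
    fdrs = bh_adjust([r.p_value for r in results])
    for r, q in zip(results, fdrs):
        r.fdr = float(q)
        r.significant = (r.fdr < params.fdr_max) and (r.logfc > params.logfc_min)
    return results


def select_significant_contigs(
    de_results: Optional[Sequence[DEResult]],
    matrix: MatchedECMatrix,
    params: DEParams,
    controls_present: bool = True,
) -> Set[str]:
    """Contigs associated with retained ECs.

    With controls: the union of members of significant ECs. Without
    controls DE is skipped and contigs of every EC passing the case-CPM
    filter are returned.
    """
    if controls_present:
        if de_results is None:
            raise ValueError("DE results required when controls are present")
        out: Set[str] = set()
        for r in de_results:
            if r.significant:
                out.update(r.ec)
        return out
    filtered = filter_low_expression(matrix, params)
    out = set()
    for ec in filtered.ec_list:
        out.update(ec)
    return out


def de_results_table(results: Sequence[DEResult]):
    import pandas as pd

    return pd.DataFrame(
        {
            "ec_members": [",".join(r.ec) for r in results],
            "case_count": [r.case_count for r in results],
            "control_counts": [",".join(map(str, r.control_counts)) for r in results],
            "case_cpm": [r.case_cpm for r in results],
            "logFC": [r.logfc for r in results],
            "lrt_stat": [r.lrt_stat for r in results],
            "p_value": [r.p_value for r in results],
            "FDR": [r.fdr for r in results],
            "significant": [r.significant for r in results],
        }
    )
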