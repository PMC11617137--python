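"""Shuffle-null log Bayes factors and the credibility criterion.

The per-component log evidences from the pattern component fit have no
intrinsic scale, so they are referenced to a permutation null: the 8
condition labels of each subject's U matrix are shuffled (voxel order
untouched) K times — the same permutation applied to every subject — and the
whole fit + model-reduction + group pipeline is rerun each time.  Subtracting
the real (correct-label) group log evidence from each shuffled one gives a
distribution of log Bayes factors (LBF) in which larger values mean the real
labels carry more evidence.  A component is called credible at the 80% or
95% level when its median LBF beats the corresponding quantile of the
median-centered null by at least ln(3) — "three times more credible" on the
evidence scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .components import ComponentModel, build_components
from .core import (
    PRIOR_MEAN,
    PRIOR_VAR,
    REDUCED_MEAN,
    REDUCED_VAR,
    _bmr_delta_f,
    _prepare_problem,
    fit_gram_batch,
    second_moment,
)
from .glm import PatternMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "LN3",
    "NullDistribution",
    "ComponentSummary",
    "EvidenceReport",
    "shuffle_null",
    "log_bayes_factors",
    "hdi",
    "credibility",
    "evidence_report",
    "report_table",
]

#: "Three times more credible" on the natural-log evidence scale.
LN3 = float(np.log(3.0))


@dataclass
class NullDistribution:
    """Real and shuffled group log evidences, per component.

    ``real`` is the identity-permutation (iteration 0) result, bitwise equal
    to running the pipeline without shuffling; ``null`` holds the K shuffled
    group log evidences (more negative = stronger apparent contribution).
    """

    names: tuple[str, ...]
    real: dict[str, float]
    null: np.ndarray  # (K, n_components)
    permutations: np.ndarray  # (K + 1, 8), row 0 = identity
    rng_seed: int | None = None

    @property
    def K(self) -> int:
        return self.null.shape[0]

    def null_for(self, name: str) -> np.ndarray:
        return self.null[:, self.names.index(name)]


def _draw_permutations(K: int, n_conditions: int, rng: np.random.Generator) -> np.ndarray:
    """K random non-identity permutations, drawn with replacement."""
    identity = np.arange(n_conditions)
    perms = np.empty((K, n_conditions), dtype=int)
    for k in range(K):
        p = rng.permutation(n_conditions)
        while np.array_equal(p, identity):
            p = rng.permutation(n_conditions)
        perms[k] = p
    return perms


def shuffle_null(
    subject_patterns: list[PatternMatrix | np.ndarray],
    components: list[ComponentModel] | None = None,
    K: int = 1000,
    rng_seed: int | np.random.Generator = 0,
    center: bool = True,
    method: str = "refit",
    prior_mean: float = PRIOR_MEAN,
    prior_var: float = PRIOR_VAR,
    tol: float = 1e-4,
    max_iter: int = 128,
) -> NullDistribution:
    """Group log evidences under K condition-label shuffles (plus the identity).

    One permutation per iteration, shared across subjects (preserving
    group-level exchangeability).  The fits for all permutations and subjects
    run as a single batched ReML problem: shuffling labels in U permutes the
    rows/columns of its second-moment matrix, which is all the likelihood
    needs.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if components is None:
        components = build_components()
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    Us = [
        pm.values if isinstance(pm, PatternMatrix) else np.asarray(pm, float)
        for pm in subject_patterns
    ]
    n_subj = len(Us)
    if n_subj < 1:
        raise ValueError("need at least one subject")
    d = Us[0].shape[0]
    grams = [second_moment(U, center=center) for U in Us]
    n_vox = np.array([g.n_voxels for g in grams], dtype=float)

    perms = np.vstack([np.arange(d), _draw_permutations(K, d, rng)])

    # Batch layout: index b = k * n_subj + s.
    S8 = np.stack(
        [g.G[np.ix_(p, p)] for p in perms for g in grams]
    )
    Sp, Q, names = _prepare_problem(S8, components, center)
    m = Q.shape[0]
    n_b = np.tile(n_vox, perms.shape[0])
    pm_vec = np.full(m, prior_mean, dtype=float)
    pv_vec = np.full(m, prior_var, dtype=float)
    h, C, F, ll, iters, conv = fit_gram_batch(
        Sp, n_b, Q, pm_vec, pv_vec, tol=tol, max_iter=max_iter
    )
    if not conv.all():
        logger.warning("%d of %d shuffle fits did not converge", (~conv).sum(), len(conv))

    n_comp = m - 1
    B = Sp.shape[0]
    dF = np.empty((B, n_comp))
    if method == "refit":
        # One batched call for all (component, permutation, subject) refits,
        # warm-started at the full posterior mode with one coordinate pinned.
        pm_r = np.tile(pm_vec, (n_comp * B, 1))
        pv_r = np.tile(pv_vec, (n_comp * B, 1))
        h0 = np.tile(h, (n_comp, 1))
        for i in range(n_comp):
            sl = slice(i * B, (i + 1) * B)
            pm_r[sl, i] = REDUCED_MEAN
            pv_r[sl, i] = REDUCED_VAR
            h0[sl, i] = REDUCED_MEAN
        _, _, F_red, _, _, conv_r = fit_gram_batch(
            np.tile(Sp, (n_comp, 1, 1)), np.tile(n_b, n_comp), Q, pm_r, pv_r,
            tol=tol, max_iter=max_iter, h_init=h0,
        )
        if not conv_r.all():
            logger.warning("%d reduced refits did not converge", (~conv_r).sum())
        dF[:] = (F_red - np.tile(F, n_comp)).reshape(n_comp, B).T
    elif method == "bmr":
        for i in range(n_comp):
            dF[:, i] = _bmr_delta_f(h, C, pm_vec, pv_vec, reduce_idx=i)
    else:
        raise ValueError(f"unknown method {method!r}; expected 'refit' or 'bmr'")
    group_dF = dF.reshape(perms.shape[0], n_subj, n_comp).sum(axis=1)

    comp_names = names[:-1]
    return NullDistribution(
        names=comp_names,
        real={n: float(v) for n, v in zip(comp_names, group_dF[0])},
        null=group_dF[1:],
        permutations=perms,
        rng_seed=rng_seed if isinstance(rng_seed, int) else None,
    )


def log_bayes_factors(null: NullDistribution) -> dict[str, np.ndarray]:
    """LBF_k = dF_shuffled,k - dF_real per component.

    With the more-negative-is-stronger evidence convention, positive LBFs
    mean the real labels carry more evidence than the shuffled ones.
    """
    return {
        name: null.null_for(name) - null.real[name] for name in null.names
    }


def hdi(samples: np.ndarray, mass: float = 0.95) -> tuple[float, float]:
    """Shortest interval containing ``mass`` of an empirical sample."""
    x = np.sort(np.asarray(samples, dtype=float))
    n = len(x)
    k = max(1, int(np.ceil(mass * n)))  # number of points the interval must cover
    if k >= n:
        return float(x[0]), float(x[-1])
    widths = x[k - 1 :] - x[: n - k + 1]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + k - 1])


def credibility(
    lbf: np.ndarray, null_values: np.ndarray, level: float
) -> tuple[bool, float]:
    """Apply the ln(3)-beyond-the-null-quantile credibility rule.

    The null LBF reference set is the shuffled log evidences centered on
    their own median; the component is credible at ``level`` iff
    ``median(lbf) >= ln(3) + quantile(null reference, level)``.  Returns
    ``(flag, threshold)``.
    """
    if level not in (0.80, 0.95):
        raise ValueError("level must be 0.80 or 0.95")
    null_ref = null_values - np.median(null_values)
    threshold = LN3 + float(np.quantile(null_ref, level))
    return bool(np.median(lbf) >= threshold), threshold


@dataclass
class ComponentSummary:
    name: str
    real_log_evidence: float
    median_lbf: float
    hdi_low: float
    hdi_high: float
    threshold_80: float
    threshold_95: float
    credible_80: bool
    credible_95: bool


@dataclass
class EvidenceReport:
    """Per-component LBF summaries and credibility flags for one ROI/epoch."""

    components: dict[str, ComponentSummary]
    K: int
    roi: str | None = None
    epoch: str | None = None

    def flags(self, level: float) -> dict[str, bool]:
        attr = {0.80: "credible_80", 0.95: "credible_95"}[level]
        return {n: getattr(c, attr) for n, c in self.components.items()}


def evidence_report(
    null: NullDistribution,
    roi: str | None = None,
    epoch: str | None = None,
    hdi_mass: float = 0.95,
) -> EvidenceReport:
    """Summarize a shuffle null into median LBF, HDI and 80/95% flags."""
    lbfs = log_bayes_factors(null)
    out = {}
    for name in null.names:
        lbf = lbfs[name]
        nv = null.null_for(name)
        flag80, thr80 = credibility(lbf, nv, 0.80)
        flag95, thr95 = credibility(lbf, nv, 0.95)
        lo, hi = hdi(lbf, hdi_mass)
        out[name] = ComponentSummary(
            name=name,
            real_log_evidence=null.real[name],
            median_lbf=float(np.median(lbf)),
            hdi_low=lo,
            hdi_high=hi,
            threshold_80=thr80,
            threshold_95=thr95,
            credible_80=flag80,
            credible_95=flag95,
        )
    return EvidenceReport(components=out, K=null.K, roi=roi, epoch=epoch)


def report_table(reports: list[EvidenceReport]):
    """Stack evidence reports into a tidy table (one row per ROI/epoch/component)."""
    import pandas as pd

    rows = []
    for rep in reports:
        for name, c in rep.components.items():
            rows.append(
                {
                    "roi": rep.roi,
                    "epoch": rep.epoch,
                    "component": name,
                    "real_log_evidence": c.real_log_evidence,
                    "median_lbf": c.median_lbf,
                    "hdi_low": c.hdi_low,
                    "hdi_high": c.hdi_high,
                    "credible_80": c.credible_80,
                    "credible_95": c.credible_95,
                    "asterisk": "*" if c.credible_95 else ("(*)" if c.credible_80 else ""),
                    "K": rep.K,
                }
            )
    return pd.DataFrame(rows)


def plot_report(report: EvidenceReport, ax=None):
    """Bar plot of median LBFs with HDI error bars and credibility asterisks."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 3.5))
    names = list(report.components)
    med = [report.components[n].median_lbf for n in names]
    lo = [report.components[n].hdi_low for n in names]
    hi = [report.components[n].hdi_high for n in names]
    x = np.arange(len(names))
    err = np.vstack([np.array(med) - lo, np.array(hi) - med])
    ax.bar(x, med, yerr=err, capsize=3, color="0.6")
    for i, n in enumerate(names):
        c = report.components[n]
        if c.credible_95:
            ax.annotate("*", (i, hi[i]), ha="center", color="black", fontsize=14)
        elif c.credible_80:
            ax.annotate("*", (i, hi[i]), ha="center", color="0.5", fontsize=14)
    ax.set_xticks(x, names, rotation=45, ha="right")
    ax.set_ylabel("log Bayes factor")
    title = " / ".join(s for s in (report.roi, report.epoch) if s)
    if title:
        ax.set_title(title)
    return ax
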