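"""Bivariate genetic/environmental correlation between measure pairs.

The phenotypic correlation between traits a and b decomposes as

    rho_P = sqrt(h2_a * h2_b) * rho_G
            + sqrt((1 - h2_a) * (1 - h2_b)) * rho_E

where ``rho_G`` is the correlation of the genetic influences on the two
traits and ``rho_E`` the environmental analogue.  ``rho_G`` is identified
from the cross-twin cross-trait (CTCT) contrast: the correlation between
twin 1's trait a and twin 2's trait b is ``rG_pair * cov_G(a, b)`` with
``rG_pair`` 1.0 for MZ and 0.5 for DZ pairs, so the genetic covariance is
``2 * (ctct_MZ - ctct_DZ)`` — a moment (Falconer-style bivariate) estimator
that replaces pedigree maximum likelihood; it needs twin pairs only and
matches the assumptions of the univariate stage.

Inputs are expected covariate-residualized and inverse-normal transformed
(see :func:`prepare_phenotypes`).  ``rho_G`` is clamped to [-1, 1] with each
clamp logged rather than raised; cells with out-of-range heritability are
masked with a reason code.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .heritability import falconer, twin_correlations
from .preprocess import inverse_normal_transform_frame, residualize, zscore
from .synthetic_data import Cohort


class GeneCorrError(ValueError):
    pass


@dataclass
class GeneticCorrelationMatrix:
    rho_G: pd.DataFrame
    rho_E: pd.DataFrame
    rho_P: pd.DataFrame
    mask: pd.DataFrame           # True where the cell is defined
    reasons: dict = field(default_factory=dict)   # (a, b) -> why masked
    clamped: list = field(default_factory=list)   # (a, b, raw_value) clamp log

    def to_long(self) -> pd.DataFrame:
        """Heatmap-ready long format: measure_a, measure_b, rho_G, rho_E, rho_P."""
        rows = []
        for a in self.rho_G.index:
            for b in self.rho_G.columns:
                rows.append({
                    "measure_a": a, "measure_b": b,
                    "rho_G": self.rho_G.loc[a, b],
                    "rho_E": self.rho_E.loc[a, b],
                    "rho_P": self.rho_P.loc[a, b],
                    "defined": bool(self.mask.loc[a, b]),
                })
        return pd.DataFrame(rows)


def prepare_phenotypes(cohort: Cohort) -> pd.DataFrame:
    """Standard preprocessing for the genetic-correlation stage.

    Residualize on [1, age, sex, age*sex, age^2, age^2*sex], then apply the
    rank-based inverse normal transform, then z-score.
    """
    subj = cohort.subjects.set_index("subject_id").loc[cohort.phenotypes.index]
    resid = residualize(cohort.phenotypes, subj["age"].to_numpy(),
                        subj["sex"].to_numpy())
    return zscore(inverse_normal_transform_frame(resid))


def cross_twin_cross_trait(cohort: Cohort, phenotypes: pd.DataFrame,
                           trait_a: str, trait_b: str) -> tuple[float, float]:
    """Double-entered correlation of twin1's trait a with twin2's trait b.

    Returns ``(ctct_MZ, ctct_DZ)``.  With ``trait_b == trait_a`` this reduces
    to the univariate twin correlations.
    """
    out = []
    for zyg in ("MZ", "DZ"):
        pairs = cohort.twin_pairs(zyg)
        if len(pairs) < 3:
            raise GeneCorrError(f"need >= 3 {zyg} pairs")
        a = phenotypes[trait_a]
        b = phenotypes[trait_b]
        x = np.concatenate([[a[t1] for t1, _ in pairs], [a[t2] for _, t2 in pairs]])
        y = np.concatenate([[b[t2] for _, t2 in pairs], [b[t1] for t1, _ in pairs]])
        if np.std(x) == 0 or np.std(y) == 0:
            raise GeneCorrError(f"degenerate variance for {trait_a}/{trait_b}")
        out.append(float(np.corrcoef(x, y)[0, 1]))
    return out[0], out[1]


def decompose(rho_p: float, h2a: float, h2b: float,
              genetic_cov: float) -> tuple[float, float, bool]:
    """Split a phenotypic correlation into genetic and environmental parts.

    ``rho_G = genetic_cov / sqrt(h2a * h2b)`` (clamped to [-1, 1]);
    ``rho_E`` is solved from the decomposition so that recomposition returns
    ``rho_P`` exactly whenever no clamping occurred.  Returns
    ``(rho_G, rho_E, was_clamped)``.
    """
    if not (0.0 < h2a < 1.0) or not (0.0 < h2b < 1.0):
        raise GeneCorrError(f"heritabilities must lie in (0, 1); got {h2a}, {h2b}")
    gg = np.sqrt(h2a * h2b)
    ee = np.sqrt((1.0 - h2a) * (1.0 - h2b))
    rho_g = genetic_cov / gg
    clamped = not (-1.0 <= rho_g <= 1.0)
    rho_g = float(np.clip(rho_g, -1.0, 1.0))
    rho_e = float((rho_p - gg * rho_g) / ee)
    return rho_g, rho_e, clamped


H2_TRUNCATION = (0.01, 0.99)


def genetic_correlation_matrix(cohort: Cohort,
                               phenotypes: pd.DataFrame | None = None,
                               h2: pd.Series | None = None
                               ) -> GeneticCorrelationMatrix:
    """All-pairs genetic/environmental correlation matrices for a cohort.

    Heritabilities default to the classical Falconer estimates computed on
    the same (prepared) phenotypes; raw values outside (0, 1) mask the
    affected cells, values inside are truncated to [0.01, 0.99] before use.
    """
    if phenotypes is None:
        phenotypes = prepare_phenotypes(cohort)
    measures = list(phenotypes.columns)

    if h2 is None:
        corr = twin_correlations(cohort, phenotypes)
        h2 = pd.Series(
            {m: falconer(corr.loc[m, "rMZ"], corr.loc[m, "rDZ"])[0]
             for m in measures})
    usable = (h2 > 0.0) & (h2 < 1.0)
    h2_used = h2.clip(*H2_TRUNCATION)

    n = len(measures)
    rho_g = pd.DataFrame(np.full((n, n), np.nan), index=measures, columns=measures)
    rho_e = rho_g.copy()
    rho_p = pd.DataFrame(np.corrcoef(phenotypes.to_numpy().T),
                         index=measures, columns=measures)
    mask = pd.DataFrame(False, index=measures, columns=measures)
    reasons: dict = {}
    clamp_log: list = []

    for i, a in enumerate(measures):
        for b in measures[i:]:
            if not (usable[a] and usable[b]):
                reasons[(a, b)] = "heritability outside (0,1)"
                continue
            if a == b:
                rho_g.loc[a, b] = 1.0
                rho_e.loc[a, b] = 1.0
                mask.loc[a, b] = True
                continue
            try:
                ctct_mz, ctct_dz = cross_twin_cross_trait(cohort, phenotypes, a, b)
            except GeneCorrError as exc:
                reasons[(a, b)] = str(exc)
                continue
            gcov = 2.0 * (ctct_mz - ctct_dz)
            g, e, was_clamped = decompose(rho_p.loc[a, b], h2_used[a], h2_used[b], gcov)
            if was_clamped:
                clamp_log.append((a, b, gcov / np.sqrt(h2_used[a] * h2_used[b])))
            rho_g.loc[a, b] = rho_g.loc[b, a] = g
            rho_e.loc[a, b] = rho_e.loc[b, a] = e
            mask.loc[a, b] = mask.loc[b, a] = True

    return GeneticCorrelationMatrix(rho_G=rho_g, rho_E=rho_e, rho_P=rho_p,
                                    mask=mask, reasons=reasons, clamped=clamp_log)
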