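"""Classical twin-correlation heritability.

Falconer's formula estimates additive heritability as ``h2 = 2*(rMZ - rDZ)``.
Model selection follows the either/or convention of the classical twin
design: when the MZ correlation exceeds twice the DZ correlation the common
environment is assumed negligible (ADE model) and ``rMZ`` itself is taken as
the broad genetic estimate; when ``rMZ < rDZ`` no genetic model fits and the
(negative) Falconer value is flagged.  Twin correlations are computed on
double-entered pairs — each pair contributes both orderings — so estimates
are invariant to within-pair ordering (equivalent in spirit to an intraclass
correlation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .synthetic_data import Cohort


class HeritabilityError(ValueError):
    pass


MODEL_ACE = "ACE"
MODEL_ADE = "ADE"
MODEL_NONE = "NONE"


def twin_correlation(pairs: np.ndarray) -> float:
    """Double-entry Pearson correlation of an (n_pairs, 2) value array."""
    pairs = np.asarray(pairs, dtype=float)
    if pairs.ndim != 2 or pairs.shape[1] != 2:
        raise HeritabilityError("pairs must be an (n_pairs, 2) array")
    if pairs.shape[0] < 3:
        raise HeritabilityError("need at least 3 pairs")
    x = np.concatenate([pairs[:, 0], pairs[:, 1]])
    y = np.concatenate([pairs[:, 1], pairs[:, 0]])
    if np.std(x) == 0 or np.std(y) == 0:
        raise HeritabilityError("zero variance in twin values")
    return float(np.corrcoef(x, y)[0, 1])


def falconer(r_mz: float, r_dz: float) -> tuple[float, str, float]:
    """Falconer heritability with ACE/ADE/NONE model selection.

    Returns ``(h2, model, h2_falconer)`` where ``h2_falconer`` is always
    ``2*(rMZ - rDZ)`` and ``h2`` is the headline estimate: the Falconer value
    under ACE (and, flagged, under NONE), or ``rMZ`` under ADE.  The boundary
    ``rMZ == 2*rDZ`` classifies as ACE (dominance assumed negligible there).
    """
    for name, r in (("rMZ", r_mz), ("rDZ", r_dz)):
        if not -1.0 <= r <= 1.0:
            raise HeritabilityError(f"{name} must be in [-1, 1], got {r}")
    h2_falc = 2.0 * (r_mz - r_dz)
    if r_mz < r_dz:
        return h2_falc, MODEL_NONE, h2_falc
    if r_mz <= 2.0 * r_dz:
        return h2_falc, MODEL_ACE, h2_falc
    return r_mz, MODEL_ADE, h2_falc


def reliability(test: pd.DataFrame, retest: pd.DataFrame) -> pd.Series:
    """Per-measure Pearson test-retest correlation over matched subjects."""
    common = test.index.intersection(retest.index)
    if len(common) < 3:
        raise HeritabilityError("need at least 3 matched test-retest subjects")
    out = {}
    for col in test.columns:
        a = test.loc[common, col].to_numpy(float)
        b = retest.loc[common, col].to_numpy(float)
        if np.std(a) == 0 or np.std(b) == 0:
            raise HeritabilityError(f"zero variance in measure {col!r}")
        out[col] = float(sps.pearsonr(a, b)[0])
    return pd.Series(out, name="reliability")


def disattenuate(h2: float, rel: float) -> tuple[float, bool]:
    """Correct an estimate for measurement error by dividing by reliability.

    Returns ``(h2 / rel, inflated)`` where ``inflated`` flags corrected
    values above 1 — poor reliability can artificially inflate heritability,
    so such values should be read with caution.
    """
    if rel <= 0:
        raise HeritabilityError(f"reliability must be > 0, got {rel}")
    corrected = h2 / rel
    return corrected, corrected > 1.0


@dataclass
class HeritabilityProfile:
    """One heritability value per measure from one method.

    ``method`` is one of {falconer, univariate, ridge, rf}; ``table`` holds
    per-measure columns and ``values`` exposes the headline estimate vector
    used for cross-method comparison.
    """

    method: str
    table: pd.DataFrame
    value_column: str = "h2"

    @property
    def values(self) -> pd.Series:
        return self.table[self.value_column]

    @property
    def measures(self) -> list[str]:
        return list(self.table.index)

    def to_tsv(self, path) -> None:
        out = self.table.copy()
        out.index.name = "measure"
        out.to_csv(path, sep="\t")


def _pair_values(cohort: Cohort, measure: str, zygosity: str) -> np.ndarray:
    pairs = cohort.twin_pairs(zygosity)
    pheno = cohort.phenotypes[measure]
    return np.array([[pheno[t1], pheno[t2]] for t1, t2 in pairs])


def twin_correlations(cohort: Cohort,
                      phenotypes: pd.DataFrame | None = None
                      ) -> pd.DataFrame:
    """Per-measure double-entry rMZ and rDZ for a cohort."""
    data = cohort.phenotypes if phenotypes is None else phenotypes
    mz = cohort.twin_pairs("MZ")
    dz = cohort.twin_pairs("DZ")
    if len(mz) < 3 or len(dz) < 3:
        raise HeritabilityError("need at least 3 pairs of each zygosity")
    rows = {}
    for col in data.columns:
        vals = data[col]
        r_mz = twin_correlation(np.array([[vals[a], vals[b]] for a, b in mz]))
        r_dz = twin_correlation(np.array([[vals[a], vals[b]] for a, b in dz]))
        rows[col] = {"rMZ": r_mz, "rDZ": r_dz}
    return pd.DataFrame(rows).T


def falconer_profile(cohort: Cohort,
                     phenotypes: pd.DataFrame | None = None,
                     domains: pd.Series | None = None,
                     rel: pd.Series | None = None) -> HeritabilityProfile:
    """Full classical profile: rMZ, rDZ, model, h2, optional disattenuation.

    For ADE-pattern measures both the headline ``h2`` (= rMZ) and the
    Falconer-form ``h2_falconer`` are stored, since either may be the
    quantity of interest downstream.
    """
    corr = twin_correlations(cohort, phenotypes)
    records = {}
    for measure, row in corr.iterrows():
        h2, model, h2_falc = falconer(row["rMZ"], row["rDZ"])
        rec = {"rMZ": row["rMZ"], "rDZ": row["rDZ"], "model": model,
               "h2": h2, "h2_falconer": h2_falc}
        if domains is not None and measure in domains.index:
            rec["domain"] = domains[measure]
        if rel is not None and measure in rel.index:
            corrected, inflated = disattenuate(h2, rel[measure])
            rec["reliability"] = rel[measure]
            rec["h2_disattenuated"] = corrected
            rec["disattenuation_inflated"] = inflated
        records[measure] = rec
    table = pd.DataFrame(records).T
    return HeritabilityProfile(method="falconer", table=table)
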