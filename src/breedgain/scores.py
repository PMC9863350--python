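"""Overall performance and yield-stability statistics from a rotated
factor-analytic fit, expressed in trait units.

Overall performance (OP) generalises a genotype main effect when scale
differs across environments:  OP_i = mean first-factor loading x the
genotype's first-factor score.  It is a valid main-effect measure only
when the first-factor loadings share one sign across sites; with crossover
interaction (mixed signs) OP is still computed but flagged.

Stability is the root-mean-square deviation (RMSD) of a genotype's
site effects from the regression line associated with factor 1: the
deviations are d_ij = sum_{k>=2} lambda_jk f_ik over the trait's p sites
and RMSD_i = sqrt(mean_j d_ij^2).  Under an FA(2) fit RMSD is exactly
proportional to |f_2|; smaller RMSD means a more stable genotype.
Site-specific (Psi) effects are measurement-like and excluded.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from breedgain.met import FAFit, pbv_across_env

__all__ = ["overall_performance", "stability_rmsd", "selection_scores"]


def _require_rotated(fit: FAFit) -> None:
    if fit.k == 0:
        raise ValueError("requires a factor-analytic fit (k >= 1)")
    if not fit.rotated:
        raise ValueError("fit must be rotated first (met.rotate_loadings)")


def overall_performance(fit: FAFit) -> pd.Series:
    """OP_i = mean(lambda_1) * f_i1, in trait units.

    Warns when first-factor loadings have mixed signs across sites, in
    which case OP is not a valid generalised main effect (crossover
    genotype-by-environment interaction).
    """
    _require_rotated(fit)
    lam1 = fit.loadings[:, 0]
    if np.any(lam1 < 0) and np.any(lam1 > 0):
        warnings.warn(
            "first-factor loadings have mixed signs across sites; "
            "OP is not a valid generalised main effect for this trait",
            stacklevel=2,
        )
    op = lam1.mean() * fit.scores[:, 0]
    return pd.Series(op, index=fit.genotypes, name="OP")


def stability_rmsd(fit: FAFit) -> pd.Series:
    """RMSD_i = sqrt((1/p) sum_j (sum_{k>=2} lambda_jk f_ik)^2).

    Identically zero under an FA(1) optimum (no higher factors to deviate
    along); invariant to the sign convention of factors 2..k.
    """
    _require_rotated(fit)
    p = len(fit.sites)
    if fit.k == 1:
        return pd.Series(np.zeros(len(fit.genotypes)), index=fit.genotypes, name="RMSD")
    d = fit.scores[:, 1:] @ fit.loadings[:, 1:].T  # genotypes x sites
    rmsd = np.sqrt(np.mean(d**2, axis=1))
    return pd.Series(rmsd, index=fit.genotypes, name="RMSD")


def selection_scores(fit: FAFit) -> pd.DataFrame:
    """Per-genotype PBV, OP, RMSD and factor scores for one trait."""
    _require_rotated(fit)
    out = pd.DataFrame(
        {
            "PBV": pbv_across_env(fit),
            "OP": overall_performance(fit),
            "RMSD": stability_rmsd(fit),
        }
    )
    for k in range(fit.k):
        out[f"f{k + 1}"] = fit.scores[:, k]
    return out
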