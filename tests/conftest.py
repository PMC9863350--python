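"""Shared fixtures: small pedigrees and a reusable factor-analytic fit."""

import numpy as np
import pandas as pd
import pytest

from breedgain import met
from breedgain.pedigree import PedigreeRecord, build_additive_matrix


@pytest.fixture(scope="session")
def random_pedigree():
    """30-member pedigree mixing crosses and selfings over founders with
    varied base inbreeding."""
    rng = np.random.default_rng(42)
    recs = [PedigreeRecord(f"F{i}", fgen=int(rng.integers(0, 6))) for i in range(8)]
    ids = [r.id for r in recs]
    for i in range(22):
        if rng.random() < 0.25:  # selfing
            p = str(rng.choice(ids))
            recs.append(PedigreeRecord(f"G{i}", p, p))
        else:
            a, b = rng.choice(ids, 2, replace=False)
            recs.append(PedigreeRecord(f"G{i}", str(a), str(b)))
        ids.append(f"G{i}")
    return recs


def make_fa_truth(n_founders=30, n_geno=120, p=4, seed=0, k=2, reps=2,
                  s2na=0.08, s2e=0.25, lam2_range=(0.15, 0.4)):
    """Simulated plot data with known FA(k) additive truth over a pedigree.

    Returns (plots, relationship matrix, true G, s2na vector, s2e vector).
    """
    rng = np.random.default_rng(seed)
    recs = [PedigreeRecord(f"F{i}", fgen=0) for i in range(n_founders)]
    ids = [r.id for r in recs]
    for i in range(n_geno):
        a, b = rng.choice(n_founders, 2, replace=False)
        recs.append(PedigreeRecord(f"G{i}", f"F{a}", f"F{b}"))
    rm = build_additive_matrix(recs)
    all_ids = [r.id for r in recs]
    A = rm.a

    lam = np.zeros((p, k))
    lam[:, 0] = rng.uniform(0.45, 0.8, p)
    if k >= 2:
        lam[:, 1] = rng.uniform(*lam2_range, p) * np.where(np.arange(p) < p // 2, 1, -1)
    psi = rng.uniform(0.03, 0.10, p)
    G = lam @ lam.T + np.diag(psi)

    L = np.linalg.cholesky(A + 1e-10 * np.eye(len(A)))
    LG = np.linalg.cholesky(G)
    U = L @ rng.standard_normal((len(A), p)) @ LG.T

    s2na_v = np.full(p, s2na)
    s2e_v = np.full(p, s2e)
    rows = []
    observed = all_ids[n_founders:]  # phenotype the offspring only
    for j in range(p):
        for g in observed:
            gi = rm.index[g]
            na = rng.normal(0, np.sqrt(s2na_v[j]))
            for _ in range(reps):
                rows.append(
                    {
                        "site": f"S{j}",
                        "genotype": g,
                        "value": 2.0 + 0.3 * j + U[gi, j] + na
                        + rng.normal(0, np.sqrt(s2e_v[j])),
                    }
                )
    return pd.DataFrame(rows), rm, G, s2na_v, s2e_v, lam, psi


@pytest.fixture(scope="session")
def fa2_recovery_errors():
    """Frobenius relative errors of the fitted LL'+Psi against truth on
    FA(2) datasets of 200 genotypes x 4 sites (computed once, shared)."""
    errs = []
    for seed in (11, 21, 22):
        plots, rm, G, *_ = make_fa_truth(n_geno=200, n_founders=40, seed=seed)
        data = met.METDataset.from_plots(plots, rm)
        fit = met.fit_fa_model(data, 2)
        errs.append(
            float(np.linalg.norm(fit.genetic_covariance - G) / np.linalg.norm(G))
        )
    return errs


@pytest.fixture(scope="session")
def fa2_fit():
    """One FA(2) dataset with its fitted (and rotated) model, shared by the
    rotation / scores / correlation tests."""
    plots, rm, G, s2na, s2e, lam, psi = make_fa_truth(seed=11)
    data = met.METDataset.from_plots(plots, rm)
    base = met.fit_base_model(data)
    fit = met.fit_fa_model(data, 2, base=base)
    return {
        "data": data,
        "base": base,
        "fit": fit,
        "rotated": met.rotate_loadings(fit),
        "G_true": G,
        "s2na": s2na,
        "s2e": s2e,
    }
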