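"""Stochastic simulator of augmented S0,1 family recurrent selection.

The simulator generates what the analysis pipeline consumes — a pedigree,
true breeding values, and plot-level multi-site phenotypes — with the
statistical structure the models assume:

* An infinitesimal model with no explicit loci.  Each genotype carries,
  per trait, a pair of latent additive factor scores; a cross's scores are
  the midparent plus a Mendelian-sampling deviation with variance
  0.5 * (1 - (F_s + F_d)/2) per unit additive variance, so deviations
  shrink to zero as parents approach homozygosity (an F1 of two fully
  inbred unrelated parents is genetically uniform).
* Genotype-by-environment interaction of rank-2 factor form: a site's
  additive genetic effect for a trait is lambda*_1 f_1 + lambda*_2 f_2
  with site loadings drawn around a trait-level mean, so a factor-analytic
  fit of order 2 has a well-defined true optimum.  One site per cycle can
  act as a disease nursery whose grain-yield loading is partially driven
  by blackleg-resistance scores.
* Partially replicated (p-rep) trials on a range x row grid: a configured
  fraction of genotypes gets a single plot, the rest two; residuals are a
  separable AR1 x AR1 spatial field plus an iid nugget; a diagonal
  nonadditive genotype-within-site effect absorbs family-bulk deviations.

Breeding proceeds in two-year cycles: matings among the current parents
(random, truncation, or optimal-contributions selection), S0 progeny
selfed once to give the phenotyped S0,1 families, one self progeny of each
used parent carried forward (cross-and-self-sib structure), optional
migrant F1s injected per cycle.  All randomness flows from a single seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from breedgain.pedigree import (
    PedigreeRecord,
    RelationshipMatrix,
    build_additive_matrix,
)

__all__ = [
    "TraitArchitecture",
    "SimConfig",
    "TrueGenotype",
    "simulate_founders",
    "make_cross",
    "simulate_trial",
    "run_breeding_program",
    "BreedingArchive",
]

TRAITS = ["GY", "DTF", "PlHt", "Oil", "ProM", "GSL", "OL", "BL", "SW100"]

#: population means in trait units (t/ha, days, cm, %, %, umol/g, %, 1-9, g)
TRAIT_MEANS = {
    "GY": 2.02, "DTF": 80.2, "PlHt": 122.7, "Oil": 44.8, "ProM": 41.1,
    "GSL": 11.3, "OL": 61.7, "BL": 5.1, "SW100": 0.325,
}

#: per-trait additive SD in trait units (sets sigma_a; heritabilities near
#: 0.3-0.5 at the default noise levels)
TRAIT_SD = {
    "GY": 0.30, "DTF": 4.0, "PlHt": 8.0, "Oil": 1.5, "ProM": 1.2,
    "GSL": 2.5, "OL": 2.0, "BL": 1.0, "SW100": 0.012,
}

# additive correlation structure: GY/BL/Oil/PlHt/DTF positively associated,
# opposed to a ProM/GSL/OL/SW100 group
_DEFAULT_CORR = np.array(
    [
        # GY   DTF   PlHt  Oil   ProM  GSL   OL    BL    SW100
        [1.00, 0.30, 0.30, 0.35, -0.25, -0.30, -0.10, 0.40, -0.10],
        [0.30, 1.00, 0.60, 0.25, -0.20, -0.10, -0.10, 0.30, -0.30],
        [0.30, 0.60, 1.00, 0.25, -0.20, -0.10, -0.10, 0.30, -0.20],
        [0.35, 0.25, 0.25, 1.00, -0.35, -0.30, 0.10, 0.30, -0.10],
        [-0.25, -0.20, -0.20, -0.35, 1.00, 0.25, 0.15, -0.20, 0.15],
        [-0.30, -0.10, -0.10, -0.30, 0.25, 1.00, 0.10, -0.20, 0.10],
        [-0.10, -0.10, -0.10, 0.10, 0.15, 0.10, 1.00, -0.10, 0.10],
        [0.40, 0.30, 0.30, 0.30, -0.20, -0.20, -0.10, 1.00, -0.10],
        [-0.10, -0.30, -0.20, -0.10, 0.15, 0.10, 0.10, -0.10, 1.00],
    ]
)


@dataclass
class TraitArchitecture:
    """Generative truth for the trait set: means, additive correlations,
    per-trait factor loadings per site and noise levels."""

    traits: list[str] = field(default_factory=lambda: list(TRAITS))
    means: dict[str, float] = field(default_factory=lambda: dict(TRAIT_MEANS))
    additive_sd: dict[str, float] = field(default_factory=lambda: dict(TRAIT_SD))
    correlation: np.ndarray = field(default_factory=lambda: _DEFAULT_CORR.copy())
    #: fraction of additive variance on factor 1 (the rest on factor 2)
    factor1_share: float = 0.85
    #: spread of site loadings around the trait-level loading
    loading_cv: float = 0.25
    #: nonadditive variance as a fraction of additive variance
    nonadditive_fraction: float = 0.3
    #: residual (plot) variance as a multiple of additive variance
    residual_fraction: float = 1.2
    #: AR1 correlations of the spatial residual field
    rho_range: float = 0.4
    rho_row: float = 0.4
    #: share of residual variance that is spatially correlated (rest nugget)
    spatial_share: float = 0.5
    #: strength with which a disease-nursery site couples GY to BL (0-1)
    disease_coupling: float = 0.5

    def __post_init__(self):
        self.correlation = np.asarray(self.correlation, float)
        t = len(self.traits)
        if self.correlation.shape != (t, t):
            raise ValueError("correlation matrix shape mismatch")
        if not np.allclose(self.correlation, self.correlation.T):
            raise ValueError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(self.correlation), 1.0):
            raise ValueError("correlation matrix must have unit diagonal")
        w = np.linalg.eigvalsh(self.correlation)
        if w.min() < -1e-8:
            raise ValueError("correlation matrix is not positive semi-definite")
        for name, v in [
            ("nonadditive_fraction", self.nonadditive_fraction),
            ("residual_fraction", self.residual_fraction),
        ]:
            if v < 0:
                raise ValueError(f"{name} must be >= 0")

    def sigma2_a(self, trait: str) -> float:
        return self.additive_sd[trait] ** 2


@dataclass
class SimConfig:
    founders_per_pool: int = 32
    cycles: int = 3
    matings_per_cycle: int = 80
    max_uses: int = 30
    sites_per_cycle: int = 2
    ranges: int = 12
    rows: int = 30
    single_rep_fraction: float = 0.6
    #: control genotypes replicated in every trial; they anchor the site
    #: fixed effects across cycles the way historical check cultivars do
    n_controls: int = 10
    migrants_per_cycle: int = 0
    pool_divergence: float = 1.0  # between-pool mean split, in sigma_a units
    selection: str = "phenotype"  # random | truncation_true | phenotype | ocs
    selected_fraction: float = 0.2
    disease_nursery: bool = True
    seed: int = 20160101

    @property
    def plots_per_site(self) -> int:
        return self.ranges * self.rows


@dataclass
class TrueGenotype:
    """Latent truth for one genotype: per-trait factor scores and inbreeding."""

    id: str
    scores: np.ndarray  # traits x 2 latent factor scores (standardised units)
    F: float = 0.0


@dataclass
class BreedingArchive:
    pedigree: list[PedigreeRecord]
    truth: dict[str, TrueGenotype]
    plots: pd.DataFrame  # all trial tables stacked; columns site, cycle, range, row, genotype, rep, <traits>
    candidates: dict[int, list[str]]  # per-cycle phenotyped candidate lists
    site_meta: pd.DataFrame
    site_loadings: dict[str, dict[str, tuple]] = field(default_factory=dict)
    relationship: RelationshipMatrix | None = None

    def true_mean_genetic_value(self, gid: str, trait: str, arch: "TraitArchitecture",
                                sites: list[str] | None = None) -> float:
        """True across-site mean additive value of a genotype for a trait,
        in trait units, from the stored site loadings."""
        tidx = arch.traits.index(trait)
        g = self.truth[gid]
        vals = []
        use = sites if sites is not None else list(self.site_loadings)
        for site in use:
            lam = self.site_loadings[site]
            l1, l2 = lam[trait]
            v = l1 * g.scores[tidx, 0] + l2 * g.scores[tidx, 1]
            if trait == "GY" and lam.get("_disease", False):
                v += lam["_coupling"] * g.scores[arch.traits.index("BL"), 0]
            vals.append(v)
        return float(np.mean(vals))

    def relationship_matrix(self) -> RelationshipMatrix:
        if self.relationship is None:
            self.relationship = build_additive_matrix(self.pedigree)
        return self.relationship


# ---------------------------------------------------------------------------
# genotype-level operations


def _draw_correlated(arch: TraitArchitecture, n: int, rng) -> np.ndarray:
    """n draws of (traits x 2) standardised factor scores with the target
    between-trait correlation applied to each factor independently."""
    L = np.linalg.cholesky(arch.correlation + 1e-10 * np.eye(len(arch.traits)))
    z = rng.standard_normal((2, n, len(arch.traits)))
    out = np.einsum("fnt,ts->fns", z, L.T)  # factor, genotype, trait
    return np.transpose(out, (1, 2, 0))  # n x traits x 2


def simulate_founders(
    arch: TraitArchitecture, config: SimConfig, seed: int | None = None
) -> tuple[list[TrueGenotype], list[PedigreeRecord]]:
    """Two pools of fully inbred elite founders (fgen = 5), with a
    configurable between-pool divergence on factor 1 of every trait."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = 2 * config.founders_per_pool
    fgen = 5
    F = 1.0 - 0.5**fgen
    # inbred base genotypes carry additive variance (1 + F) sigma2_a
    scores = _draw_correlated(arch, n, rng) * np.sqrt(1.0 + F)
    half = config.pool_divergence / 2.0
    scores[: config.founders_per_pool, :, 0] -= half
    scores[config.founders_per_pool :, :, 0] += half
    truth, records = [], []
    for i in range(n):
        pool = "SH" if i < config.founders_per_pool else "NH"
        gid = f"{pool}{(i % config.founders_per_pool) + 1:03d}"
        truth.append(TrueGenotype(gid, scores[i], F=F))
        records.append(PedigreeRecord(gid, fgen=fgen))
    return truth, records


def make_cross(
    p1: TrueGenotype,
    p2: TrueGenotype,
    child_id: str,
    child_F: float,
    rng,
) -> TrueGenotype:
    """Offspring of p1 x p2 (selfing when p1 is p2) under the infinitesimal
    model: midparent plus Mendelian sampling with variance
    0.5 * (1 - (F_s + F_d) / 2) per unit of (standardised) additive variance."""
    mid = 0.5 * (p1.scores + p2.scores)
    ms_var = 0.5 * (1.0 - 0.5 * (p1.F + p2.F))
    if ms_var > 0:
        dev = rng.standard_normal(mid.shape) * np.sqrt(ms_var)
    else:
        dev = 0.0
    return TrueGenotype(child_id, mid + dev, F=child_F)


# ---------------------------------------------------------------------------
# trial-level operations


def _site_loadings(arch: TraitArchitecture, rng, disease: bool):
    """True (lambda*_1, lambda*_2) per trait for one site, in trait units."""
    lam = {}
    for t in arch.traits:
        sd = arch.additive_sd[t]
        l1 = sd * np.sqrt(arch.factor1_share)
        l2 = sd * np.sqrt(max(1.0 - arch.factor1_share, 0.0))
        jitter = 1.0 + arch.loading_cv * rng.standard_normal()
        # factor-2 loadings are zero-centred across sites: crossover
        # interaction, which is what makes the second factor identifiable
        lam[t] = (l1 * max(jitter, 0.05), l2 * rng.standard_normal())
    if disease:
        # the nursery's GY signal is partly the BL signal: shrink the GY
        # factor-1 loading and route the removed share through BL scores
        l1, l2 = lam["GY"]
        lam["GY"] = (l1 * (1.0 - arch.disease_coupling), l2)
    return lam


def _spatial_field(ranges: int, rows: int, rho_r: float, rho_c: float, rng):
    """Matrix-normal draw with AR1 row/column correlation, unit variance."""

    def chol_ar1(m, rho):
        idx = np.arange(m)
        K = rho ** np.abs(idx[:, None] - idx[None, :])
        return np.linalg.cholesky(K + 1e-10 * np.eye(m))

    Lr = chol_ar1(ranges, rho_r)
    Lc = chol_ar1(rows, rho_c)
    return Lr @ rng.standard_normal((ranges, rows)) @ Lc.T


def simulate_trial(
    genotypes: list[TrueGenotype],
    site: str,
    arch: TraitArchitecture,
    config: SimConfig,
    rng,
    disease: bool = False,
    loadings: dict | None = None,
    cycle: int = 0,
) -> pd.DataFrame:
    """Phenotypes for one p-rep trial on the configured grid.

    Each genotype gets one or two plots (the single-rep fraction from the
    config); assignment to grid cells is randomised.  Phenotype = site mean
    + lambda*' f + nonadditive + spatial AR1xAR1 field + nugget.  BL is only
    scored at disease-nursery sites.
    """
    n_plots = config.plots_per_site
    n_g = len(genotypes)
    n_single = min(n_g, max(2 * n_g - n_plots, int(round(config.single_rep_fraction * n_g))))
    n_double = n_g - n_single
    need = n_single + 2 * n_double
    if need > n_plots:
        raise ValueError(
            f"{need} plots requested but the {config.ranges}x{config.rows} grid "
            f"has only {n_plots} cells"
        )
    lam = loadings if loadings is not None else _site_loadings(arch, rng, disease)

    order = rng.permutation(n_g)
    reps = np.ones(n_g, int)
    reps[order[: n_double]] = 2
    plot_geno = np.repeat(np.arange(n_g), reps)
    # pad unused cells by re-using random genotypes as filler checks
    n_fill = n_plots - len(plot_geno)
    if n_fill > 0:
        plot_geno = np.concatenate([plot_geno, rng.integers(0, n_g, size=n_fill)])
    rng.shuffle(plot_geno)

    rr, cc = np.meshgrid(np.arange(1, config.ranges + 1), np.arange(1, config.rows + 1),
                         indexing="ij")
    rows_out = {
        "site": site,
        "cycle": cycle,
        "range": rr.ravel(),
        "row": cc.ravel(),
        "genotype": [genotypes[g].id for g in plot_geno],
    }
    frame = pd.DataFrame(rows_out)

    tidx = {t: i for i, t in enumerate(arch.traits)}
    scores = np.stack([g.scores for g in genotypes])  # n_g x traits x 2
    for t in arch.traits:
        if t == "BL" and not disease:
            frame[t] = np.nan
            continue
        l1, l2 = lam[t]
        g_add = l1 * scores[:, tidx[t], 0] + l2 * scores[:, tidx[t], 1]
        if t == "GY" and disease and arch.disease_coupling > 0:
            # BL-susceptible genotypes yield poorly in the nursery
            bl = scores[:, tidx["BL"], 0]
            g_add = g_add + arch.disease_coupling * arch.additive_sd["GY"] * bl
        s2a = arch.sigma2_a(t)
        na = rng.standard_normal(n_g) * np.sqrt(arch.nonadditive_fraction * s2a)
        s2e = arch.residual_fraction * s2a
        spat = _spatial_field(config.ranges, config.rows, arch.rho_range, arch.rho_row, rng)
        spat = spat.ravel() * np.sqrt(arch.spatial_share * s2e)
        nug = rng.standard_normal(n_plots) * np.sqrt((1.0 - arch.spatial_share) * s2e)
        frame[t] = (
            arch.means[t] + g_add[plot_geno] + na[plot_geno] + spat + nug
        )
        if t == "BL":
            frame[t] = frame[t].clip(1.0, 9.0)
    return frame


# ---------------------------------------------------------------------------
# full program


def _economic_truth_index(arch: TraitArchitecture, geno: TrueGenotype) -> float:
    # internal truncation criterion: factor-1 GY score
    return float(geno.scores[arch.traits.index("GY"), 0])


def run_breeding_program(config: SimConfig, arch: TraitArchitecture | None = None
                         ) -> BreedingArchive:
    """Simulate the full recurrent-selection program.

    Selection modes: 'random' matings; 'truncation_true' (truncate on the
    true GY factor-1 score); 'phenotype' (truncate on the mean observed GY
    across the cycle's sites); 'ocs' (optimal-contributions selection on
    the phenotype-mean economic index at the configured target degrees).
    Cycle 1 matings are always random pairings of the founder F1s.
    """
    if arch is None:
        arch = TraitArchitecture()
    rng = np.random.default_rng(config.seed)
    truth_list, pedigree = simulate_founders(arch, config, seed=int(rng.integers(2**31)))
    truth = {g.id: g for g in truth_list}

    # founder F1s: pair pool 1 with pool 2
    nf = config.founders_per_pool
    f1s = []
    a_rm = build_additive_matrix(pedigree)

    def coan(i, j):
        return 0.5 * a_rm.loc(i, j)

    for i in range(nf):
        sid, nid = truth_list[i].id, truth_list[nf + i].id
        cid = f"F1_{i + 1:03d}"
        child_F = coan(sid, nid)
        pedigree.append(PedigreeRecord(cid, sid, nid))
        truth[cid] = make_cross(truth[sid], truth[nid], cid, child_F, rng)
        f1s.append(cid)

    # control cultivars: inbred checks phenotyped in every trial
    controls = []
    if config.n_controls > 0:
        ctrl_F = 1.0 - 0.5**5
        cscores = _draw_correlated(arch, config.n_controls, rng) * np.sqrt(1.0 + ctrl_F)
        for i in range(config.n_controls):
            cid = f"CTRL{i + 1:02d}"
            pedigree.append(PedigreeRecord(cid, fgen=5))
            truth[cid] = TrueGenotype(cid, cscores[i], F=ctrl_F)
            controls.append(cid)

    parents = list(f1s)
    plots_all = []
    candidates: dict[int, list[str]] = {}
    site_meta = []
    site_loadings: dict[str, dict] = {}
    counter = 0

    for cycle in range(1, config.cycles + 1):
        a_rm = build_additive_matrix(pedigree)
        # --- matings
        if cycle == 1 or config.selection == "random":
            pairs = _random_pairs(parents, config, rng)
        elif config.selection == "truncation_true":
            ranked = sorted(parents, key=lambda g: -_economic_truth_index(arch, truth[g]))
            pairs = _truncation_pairs(ranked, config, rng)
        elif config.selection == "phenotype":
            ranked = _phenotype_ranking(plots_all, parents, rng)
            pairs = _truncation_pairs(ranked, config, rng)
        elif config.selection == "ocs":
            pairs = _ocs_pairs(plots_all, parents, a_rm, config, rng)
        else:
            raise ValueError(f"unknown selection mode {config.selection!r}")

        # --- S0 progeny
        new_s0 = []
        for (f, m) in pairs:
            counter += 1
            cid = f"C{cycle}_S0_{counter:05d}"
            child_F = 0.5 * a_rm.loc(f, m)
            pedigree.append(PedigreeRecord(cid, f, m))
            truth[cid] = make_cross(truth[f], truth[m], cid, child_F, rng)
            new_s0.append(cid)

        # --- self progeny of used parents (cross-and-self-sib structure)
        selfs = []
        for pid in sorted({g for pair in pairs for g in pair}):
            counter += 1
            cid = f"C{cycle}_SF_{counter:05d}"
            child_F = 0.5 * (1.0 + truth[pid].F)
            pedigree.append(PedigreeRecord(cid, pid, pid))
            truth[cid] = make_cross(truth[pid], truth[pid], cid, child_F, rng)
            selfs.append(cid)

        # --- migrants
        migrants = []
        if config.migrants_per_cycle > 0:
            mscores = _draw_correlated(arch, config.migrants_per_cycle, rng)
            for i in range(config.migrants_per_cycle):
                counter += 1
                cid = f"C{cycle}_MIG_{counter:05d}"
                pedigree.append(PedigreeRecord(cid, fgen=0))
                truth[cid] = TrueGenotype(cid, mscores[i], F=0.0)
                migrants.append(cid)

        cohort = new_s0 + selfs + migrants
        candidates[cycle] = cohort

        # --- trials (BL scored only at the nursery site); controls ride along
        genos = [truth[g] for g in cohort + controls]
        for s in range(config.sites_per_cycle):
            disease = config.disease_nursery and s == config.sites_per_cycle - 1
            site = f"{2014 + 2 * cycle}{'AU' if s % 2 == 0 else 'CA'}{s + 1}"
            lam = _site_loadings(arch, rng, disease)
            tbl = simulate_trial(genos, site, arch, config, rng, disease=disease,
                                 loadings=lam, cycle=cycle)
            plots_all.append(tbl)
            site_meta.append({"site": site, "cycle": cycle, "disease": disease})
            rec = dict(lam)
            rec["_disease"] = disease
            rec["_coupling"] = arch.disease_coupling * arch.additive_sd["GY"] if disease else 0.0
            site_loadings[site] = rec

        parents = cohort

    plots = pd.concat(plots_all, ignore_index=True)
    return BreedingArchive(
        pedigree=pedigree,
        truth=truth,
        plots=plots,
        candidates=candidates,
        site_meta=pd.DataFrame(site_meta),
        site_loadings=site_loadings,
    )


def _random_pairs(parents, config, rng):
    pairs = []
    uses = {p: 0 for p in parents}
    for _ in range(config.matings_per_cycle):
        avail = [p for p in parents if uses[p] < config.max_uses]
        f, m = rng.choice(avail, size=2, replace=len(avail) < 2)
        pairs.append((str(f), str(m)))
        uses[str(f)] += 1
        uses[str(m)] += 1
    return pairs


def _truncation_pairs(ranked, config, rng):
    n_sel = max(2, int(round(config.selected_fraction * len(ranked))))
    pool = ranked[:n_sel]
    uses = {p: 0 for p in pool}
    pairs = []
    for _ in range(config.matings_per_cycle):
        avail = [p for p in pool if uses[p] < config.max_uses]
        if len(avail) < 2:
            avail = pool
        f, m = rng.choice(avail, size=2, replace=False)
        pairs.append((str(f), str(m)))
        uses[str(f)] += 1
        uses[str(m)] += 1
    return pairs


def _phenotype_ranking(plots_all, parents, rng):
    if not plots_all:
        return list(rng.permutation(parents))
    frame = pd.concat(plots_all, ignore_index=True)
    means = frame.groupby("genotype")["GY"].mean()
    scored = [p for p in parents if p in means.index]
    unscored = [p for p in parents if p not in means.index]
    ranked = sorted(scored, key=lambda g: -means[g])
    return ranked + list(rng.permutation(unscored))


def _ocs_pairs(plots_all, parents, a_rm, config, rng):
    from breedgain.ocs import CandidateSet, OCSConfig, optimize_matings

    frame = pd.concat(plots_all, ignore_index=True)
    means = frame.groupby("genotype")["GY"].mean()
    scored = [p for p in parents if p in means.index]
    if len(scored) < 4:
        return _random_pairs(parents, config, rng)
    sub = a_rm.submatrix(scored)
    cand = CandidateSet(
        ids=scored,
        index=means.loc[scored].to_numpy(),
        A=sub.a,
        max_uses=config.max_uses,
    )
    ocs_cfg = OCSConfig(
        n_matings=config.matings_per_cycle,
        target_degrees=45.0,
        population_size=60,
        generations=300,
        seed=int(rng.integers(2**31)),
    )
    plan = optimize_matings(cand, ocs_cfg)
    return plan.pairs
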