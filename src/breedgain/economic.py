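"""Dollar-denominated economic selection index.

Each genotype's predicted breeding values (PBV) are combined into an index
in US$ per hectare.  Grain yield (GY) enters through the grain price: its
contribution is (population mean GY + PBV GY) x price.  Every other trait t
contributes PBV_t x w$_t x total GY, where the dollar weight w$_t is a
signed percentage of the grain price per +1 unit of PBV.  An optional
stability term treats the genotype's RMSD for GY as a "PBV" with a
(negative) weight, penalising unstable genotypes.

Default weights follow the convention of a canola breeding index: seed oil
carries a 1.5% price premium per +1% oil (the market bonification rate),
protein in meal twice the oil weight, negative weights against late
flowering, tall stature and glucosinolates, a positive weight on blackleg
disease resistance, and a -20% weight on RMSD GY when stability is priced.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
import yaml

GY = "GY"
RMSD_GY = "RMSD_GY"

#: default economic weights, % of grain price per +1 unit PBV
DEFAULT_PERCENT_WEIGHTS: dict[str, float] = {
    "Oil": 1.5,
    "ProM": 3.0,
    "DTF": -1.0,
    "PlHt": -0.5,
    "BL": 2.0,
    "GSL": -1.5,
    "SW100": 0.2,
    "OL": 0.0,
}

DEFAULT_RMSD_PERCENT_WEIGHT = -20.0


@dataclass
class EconomicWeights:
    """Grain price, population mean GY, and per-trait % weights."""

    grain_price: float = 550.0  # US$ per tonne
    mean_gy: float = 2.020  # t/ha
    percent_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PERCENT_WEIGHTS)
    )
    include_rmsd: bool = True
    rmsd_percent_weight: float = DEFAULT_RMSD_PERCENT_WEIGHT

    def dollar_weight(self, trait: str) -> float:
        """w$_t = (w_t / 100) * grain price, in US$ per tonne."""
        if trait == RMSD_GY:
            return self.rmsd_percent_weight / 100.0 * self.grain_price
        return self.percent_weights[trait] / 100.0 * self.grain_price

    @classmethod
    def from_file(cls, path) -> "EconomicWeights":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(
            grain_price=float(raw.get("grain_price", 550.0)),
            mean_gy=float(raw.get("mean_gy", 2.020)),
            percent_weights={k: float(v) for k, v in raw.get("percent_weights", {}).items()},
            include_rmsd=bool(raw.get("include_rmsd", True)),
            rmsd_percent_weight=float(raw.get("rmsd_percent_weight", DEFAULT_RMSD_PERCENT_WEIGHT)),
        )

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {
                    "grain_price": self.grain_price,
                    "mean_gy": self.mean_gy,
                    "percent_weights": self.percent_weights,
                    "include_rmsd": self.include_rmsd,
                    "rmsd_percent_weight": self.rmsd_percent_weight,
                },
                fh,
            )


@dataclass
class CandidateIndex:
    """Per-genotype index decomposition, all in US$/ha except total_gy."""

    id: str
    total_gy: float
    contributions: dict[str, float]
    index_excl_rmsd: float
    index_incl_rmsd: float


def total_gy(mean_gy: float, pbv_gy: float) -> float:
    """Total grain yield = population mean + PBV, t/ha; must stay positive."""
    if mean_gy <= 0:
        raise ValueError("population mean GY must be positive")
    out = mean_gy + pbv_gy
    if out <= 0:
        raise ValueError(f"total GY {out:.3f} t/ha is not positive (PBV {pbv_gy:+.3f})")
    return out


def trait_contribution(pbv_t: float, dollar_weight: float, tot_gy: float) -> float:
    """Contribution of a non-GY trait: PBV x w$ x total GY, US$/ha."""
    return pbv_t * dollar_weight * tot_gy


def economic_index(
    pbvs: dict[str, float],
    weights: EconomicWeights,
    rmsd_gy: float | None = None,
    genotype: str = "",
) -> CandidateIndex:
    """Compute both index variants (with and without the RMSD term).

    ``pbvs`` maps trait name -> PBV in trait units and must contain ``GY``
    plus every trait with a nonzero weight; zero-weight traits may be
    absent.  ``rmsd_gy`` is the genotype's RMSD for GY in t/ha (>= 0).
    """
    if GY not in pbvs:
        raise ValueError("PBV for GY is required")
    missing = [
        t
        for t, w in weights.percent_weights.items()
        if w != 0.0 and t not in pbvs
    ]
    if missing:
        raise ValueError(f"missing PBV for weighted trait(s): {missing}")

    tot = total_gy(weights.mean_gy, pbvs[GY])
    contributions: dict[str, float] = {GY: tot * weights.grain_price}
    for trait, pct in weights.percent_weights.items():
        if trait not in pbvs:
            continue
        contributions[trait] = trait_contribution(
            pbvs[trait], pct / 100.0 * weights.grain_price, tot
        )
    excl = sum(contributions.values())

    incl = excl
    if weights.include_rmsd:
        if rmsd_gy is None:
            rmsd_gy = 0.0
        if rmsd_gy < 0:
            raise ValueError("RMSD must be non-negative")
        rmsd_contrib = trait_contribution(rmsd_gy, weights.dollar_weight(RMSD_GY), tot)
        contributions[RMSD_GY] = rmsd_contrib
        incl = excl + rmsd_contrib

    return CandidateIndex(
        id=genotype,
        total_gy=tot,
        contributions=contributions,
        index_excl_rmsd=excl,
        index_incl_rmsd=incl,
    )


def index_table(
    pbv_frame: pd.DataFrame,
    weights: EconomicWeights,
    rmsd: pd.Series | None = None,
) -> pd.DataFrame:
    """Index for every row of a genotype x trait PBV table.

    ``pbv_frame`` is indexed by genotype with trait columns; ``rmsd`` is an
    optional per-genotype RMSD GY series aligned on the same index.
    """
    rows = []
    for gid, row in pbv_frame.iterrows():
        pbvs = {t: float(v) for t, v in row.items() if pd.notna(v)}
        r = float(rmsd.loc[gid]) if rmsd is not None and gid in rmsd.index else None
        ci = economic_index(pbvs, weights, rmsd_gy=r, genotype=str(gid))
        rec = {"id": ci.id, "total_gy": ci.total_gy}
        rec.update({f"contrib_{k}": v for k, v in ci.contributions.items()})
        rec["index_excl_rmsd"] = ci.index_excl_rmsd
        rec["index_incl_rmsd"] = ci.index_incl_rmsd
        rows.append(rec)
    return pd.DataFrame(rows).set_index("id")
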