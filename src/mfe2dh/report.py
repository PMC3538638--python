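"""Per-variant mechanism integration.

Combines the three evidence channels — hydrogen-bond stability calls,
enzyme kinetics, and thermal stability — into one mechanism call per
variant:

* ``cofactor_binding_impaired`` — activity lost and the evidence points at
  the NAD⁺ site (kinetics unmeasurable without a cofactor surplus, or
  cofactor-site bonds lost);
* ``substrate_binding_impaired`` — activity lost with the substrate-binding
  signature (K_m strongly elevated and substrate-site bonds lost);
* ``stability_impaired`` — activity retained but T_m clearly lowered;
* ``mixed`` — activity loss *and* destabilization together;
* ``minor`` — neither channel crosses its threshold.

The rule set deliberately uses the kinetic signature (elevated K_m vs
unmeasurable turnover) to arbitrate between substrate- and cofactor-site
attribution when a variant loses bonds in several site classes at once:
bond accounting alone cannot separate a locally loosened NAD⁺ groove from a
disturbed substrate cavity, but K_m and the cofactor-dependence of the
assay can.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "MechanismThresholds",
    "VariantReport",
    "classify_mechanism",
    "published_panel_reports",
    "render_tables",
]


@dataclass(frozen=True)
class MechanismThresholds:
    """Decision thresholds (all configurable).

    activity_pct
        Catalytic efficiency below this percent of native ⇒ activity
        impaired (default 10%).
    stability_c
        ΔT_m (native − variant) at or above this many °C ⇒ destabilized
        (default 5 °C).
    km_fold
        K_m at or above this fold-increase over native, together with lost
        substrate-site bonds, attributes the activity loss to substrate
        binding (default 3×).
    """

    activity_pct: float = 10.0
    stability_c: float = 5.0
    km_fold: float = 3.0


#: site classes treated as substrate-binding territory (the cavity, the
#: loops above it and the catalytic-triad surroundings line the same groove)
_SUBSTRATE_SITES = frozenset({"substrate", "catalytic"})


@dataclass
class VariantReport:
    """Integrated per-variant evidence and the resulting mechanism call."""

    variant: str
    efficiency: float | None
    pct_of_native: float | None
    km_fold: float | None
    delta_tm: float
    lost_bonds: list[tuple[str, str, str]]  # (bond_id, site, scope)
    gained_bonds: list[tuple[str, str, str]]
    mechanism: str
    activity_site: str | None
    thresholds: MechanismThresholds

    def summary(self) -> str:
        eff = "n.d." if self.pct_of_native is None else f"{self.pct_of_native:.1f}% of native"
        lost = ", ".join(b for b, _, _ in self.lost_bonds) or "none"
        gained = ", ".join(b for b, _, _ in self.gained_bonds) or "none"
        return "\n".join(
            [
                f"Variant {self.variant}",
                f"  catalytic efficiency : {eff}",
                f"  delta T_m            : {self.delta_tm:+.1f} C vs native",
                f"  bonds lost vs native : {lost}",
                f"  bonds gained         : {gained}",
                f"  mechanism            : {self.mechanism}"
                + (f" (site: {self.activity_site})" if self.activity_site else ""),
            ]
        )


def classify_mechanism(
    variant: str,
    native_calls: pd.Series,
    variant_calls: pd.Series,
    sites: pd.Series,
    scopes: pd.Series,
    efficiency: float | None,
    native_efficiency: float,
    delta_tm: float,
    km: float | None = None,
    native_km: float | None = None,
    thresholds: MechanismThresholds = MechanismThresholds(),
) -> VariantReport:
    """Mechanism call for one variant.

    ``native_calls``/``variant_calls`` are +/− series indexed by bond id;
    ``sites``/``scopes`` give each bond's structural-site class and monomer
    scope.  ``efficiency=None`` means kinetics were not determinable (which
    itself is evidence: the assay needed a cofactor surplus).
    """
    if native_efficiency <= 0:
        raise ValueError("native efficiency must be positive")
    idx = native_calls.index
    missing_site = [b for b in idx if not str(sites.get(b, "")).strip()]
    if missing_site:
        raise ValueError(f"bonds without a structural-site label: {missing_site}")

    lost = [
        (b, str(sites[b]), str(scopes[b]))
        for b in idx
        if native_calls[b] == "+" and variant_calls[b] == "-"
    ]
    gained = [
        (b, str(sites[b]), str(scopes[b]))
        for b in idx
        if native_calls[b] == "-" and variant_calls[b] == "+"
    ]

    if efficiency is None:
        pct = None
        activity_impaired = True  # undeterminable kinetics = impaired by definition
    else:
        pct = 100.0 * efficiency / native_efficiency
        activity_impaired = pct < thresholds.activity_pct
    destabilized = delta_tm >= thresholds.stability_c
    km_fold = None
    if km is not None and native_km is not None and native_km > 0:
        km_fold = km / native_km

    activity_site = None
    if activity_impaired:
        lost_sites = Counter(site for _, site, _ in lost)
        substrate_losses = sum(lost_sites[s] for s in _SUBSTRATE_SITES)
        if km_fold is not None and km_fold >= thresholds.km_fold and substrate_losses:
            activity_site = "substrate"
        elif efficiency is None and lost_sites.get("cofactor", 0):
            activity_site = "cofactor"
        elif lost_sites.get("cofactor", 0) > substrate_losses:
            activity_site = "cofactor"
        elif substrate_losses:
            activity_site = "substrate"
        elif lost_sites.get("cofactor", 0):
            activity_site = "cofactor"
        else:
            activity_site = "substrate"  # residual default: the assay measures turnover

    if activity_impaired and destabilized:
        mechanism = "mixed"
    elif activity_impaired:
        mechanism = f"{activity_site}_binding_impaired"
    elif destabilized:
        mechanism = "stability_impaired"
    else:
        mechanism = "minor"

    return VariantReport(
        variant=variant,
        efficiency=efficiency,
        pct_of_native=pct,
        km_fold=km_fold,
        delta_tm=delta_tm,
        lost_bonds=lost,
        gained_bonds=gained,
        mechanism=mechanism,
        activity_site=activity_site,
        thresholds=thresholds,
    )


def published_panel_reports(
    thresholds: MechanismThresholds = MechanismThresholds(),
) -> dict[str, VariantReport]:
    """Mechanism calls for the five variants from the packaged published
    tables (kinetic constants + bond call matrix)."""
    from .datasets import load_bond_calls, load_bond_watchlist, load_kinetics_table

    kin = load_kinetics_table()
    calls = load_bond_calls()
    _, bonds = load_bond_watchlist()
    sites = bonds.set_index("bond_id")["site"]
    scopes = bonds.set_index("bond_id")["scope"]
    native_eff = float(kin.loc["NATIVE", "k_cat_over_k_m"])
    native_km = float(kin.loc["NATIVE", "k_m"])
    native_tm = float(kin.loc["NATIVE", "t_m"])

    reports: dict[str, VariantReport] = {}
    for variant in kin.index:
        if variant == "NATIVE":
            continue
        row = kin.loc[variant]
        eff = None if pd.isna(row["k_cat_over_k_m"]) else float(row["k_cat_over_k_m"])
        km = None if pd.isna(row["k_m"]) else float(row["k_m"])
        reports[variant] = classify_mechanism(
            variant,
            native_calls=calls["NATIVE"],
            variant_calls=calls[variant],
            sites=sites,
            scopes=scopes,
            efficiency=eff,
            native_efficiency=native_eff,
            delta_tm=native_tm - float(row["t_m"]),
            km=km,
            native_km=native_km,
            thresholds=thresholds,
        )
    return reports


def render_tables(
    reports: dict[str, VariantReport],
    kinetics: pd.DataFrame | None = None,
    bond_calls: pd.DataFrame | None = None,
    outdir: str | Path | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Kinetics+stability table and bond×variant matrix, optionally written
    as TSV (``variant_features.tsv``, ``bond_matrix.tsv``)."""
    if not reports:
        raise ValueError("no variant reports to render")
    from .datasets import load_bond_calls, load_bond_watchlist, load_kinetics_table

    if kinetics is None:
        kinetics = load_kinetics_table()
    if bond_calls is None:
        bond_calls = load_bond_calls()
    _, bonds = load_bond_watchlist()

    rows = []
    for variant, rep in reports.items():
        row = {
            "protein": variant,
            "pct_of_native_efficiency": (
                np.nan if rep.pct_of_native is None else round(rep.pct_of_native, 2)
            ),
            "delta_tm": rep.delta_tm,
            "n_bonds_lost": len(rep.lost_bonds),
            "n_bonds_gained": len(rep.gained_bonds),
            "mechanism": rep.mechanism,
        }
        if variant in kinetics.index:
            for col in ("v_max", "k_m", "k_cat", "k_cat_over_k_m", "t_m"):
                row[col] = kinetics.loc[variant, col]
        rows.append(row)
    features = pd.DataFrame(rows).set_index("protein")

    matrix = bond_calls.copy()
    meta = bonds.set_index("bond_id")
    matrix.insert(0, "scope", meta["scope"])
    matrix.insert(1, "site", meta["site"])

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        features.to_csv(outdir / "variant_features.tsv", sep="\t")
        matrix.to_csv(outdir / "bond_matrix.tsv", sep="\t")
    return features, matrix
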