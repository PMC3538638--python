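"""Packaged reference tables for the MFE-2 dehydrogenase variant panel.

Two published tables travel with the package as plain TSV:

* ``table1_kinetics.tsv`` — per-variant kinetic constants (V_max, K_m,
  k_cat, k_cat/K_m) and melting temperatures; blanks mark quantities that
  could not be determined (the T15A kinetics, which required a large NAD⁺
  surplus even to detect activity).
* ``table2_bonds.tsv`` / ``table2_calls.tsv`` — the 18 monitored hydrogen
  bonds (watch list with monomer scope and structural-site class) and their
  published stable (+) / fluctuating (−) calls per variant.

These are *inputs* to the analysis stages and regression anchors for the
mechanism classifier; nothing here is recomputed from structure.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .hbonds import BondWatch
from .synthetic import AssayTruth

__all__ = [
    "VARIANTS",
    "load_kinetics_table",
    "load_bond_watchlist",
    "load_bond_calls",
    "assay_truth",
]

#: Panel order: wild type first, then the five disease variants.
VARIANTS = ["NATIVE", "T15A", "N158D", "E232K", "R248C", "W249G"]


def _data_path(name: str):
    return resources.files("mfe2dh.data").joinpath(name)


def load_kinetics_table() -> pd.DataFrame:
    """Kinetic constants and T_m per variant, indexed by protein label.

    NaN marks not-determined entries.
    """
    with resources.as_file(_data_path("table1_kinetics.tsv")) as p:
        df = pd.read_csv(p, sep="\t", index_col="protein")
    return df


def load_bond_watchlist() -> tuple[list[BondWatch], pd.DataFrame]:
    """The 18 monitored hydrogen bonds as watches plus the full table
    (bond_id, addresses, scope, structural-site class)."""
    from .hbonds import load_watchlist

    with resources.as_file(_data_path("table2_bonds.tsv")) as p:
        watches, df = load_watchlist(p)
    return watches, df


def load_bond_calls() -> pd.DataFrame:
    """Published +/− call matrix, indexed by bond_id, one column per variant."""
    with resources.as_file(_data_path("table2_calls.tsv")) as p:
        df = pd.read_csv(p, sep="\t", index_col="bond_id")
    return df[VARIANTS]


def assay_truth(variant: str, noise_sd: float = 0.05) -> AssayTruth:
    """Ground-truth assay parameters for a panel member, for the synthetic
    generators.  Raises KeyError for unknown labels."""
    row = load_kinetics_table().loc[variant]
    def _opt(x):
        return None if pd.isna(x) else float(x)
    return AssayTruth(
        v_max=_opt(row["v_max"]),
        k_m=_opt(row["k_m"]),
        k_cat=_opt(row["k_cat"]),
        t_m=_opt(row["t_m"]),
        noise_sd=noise_sd,
    )
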