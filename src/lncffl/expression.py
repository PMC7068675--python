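"""Matched case/control expression bundles for the three molecular layers.

The scoring statistics need the same subjects measured in all three layers
(gene, miRNA, lncRNA): one shared Pearson correlation is computed per edge
within each group, so sample columns must align across matrices.  Matrices
are features x samples TSVs; the design file maps sample id to ``case`` or
``control`` (the original study's GDM / NGT groups).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

GROUPS = ("case", "control")


class BundleError(ValueError):
    """Inconsistent or malformed expression input."""


@dataclass
class ExpressionBundle:
    """Three feature x sample matrices sharing one ordered sample set.

    Attributes
    ----------
    gene, mirna, lncrna : pandas.DataFrame
        Real-valued expression, features as index, samples as columns.
        Columns are identical and identically ordered across the three.
    groups : pandas.Series
        Per-sample label, ``case`` or ``control``, indexed by sample id in
        column order.
    """

    gene: pd.DataFrame
    mirna: pd.DataFrame
    lncrna: pd.DataFrame
    groups: pd.Series

    zero_variance: dict[str, list[str]] = field(default_factory=dict)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.groups.index)

    @property
    def case_ids(self) -> list[str]:
        return list(self.groups.index[self.groups == "case"])

    @property
    def control_ids(self) -> list[str]:
        return list(self.groups.index[self.groups == "control"])

    def matrix(self, kind: str) -> pd.DataFrame:
        return {"gene": self.gene, "miRNA": self.mirna, "lncRNA": self.lncrna}[kind]

    def log2p1(self) -> "ExpressionBundle":
        """Return a bundle with all values mapped to log2(x + 1)."""
        return ExpressionBundle(
            gene=np.log2(self.gene + 1.0),
            mirna=np.log2(self.mirna + 1.0),
            lncrna=np.log2(self.lncrna + 1.0),
            groups=self.groups.copy(),
        )


def _read_matrix(path: str | Path, design: pd.Series, missing: str) -> pd.DataFrame:
    name = str(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str).str.strip()
    df.columns = df.columns.astype(str).str.strip()
    if df.index.duplicated().any():
        dups = sorted(df.index[df.index.duplicated()].unique())
        raise BundleError(f"{name}: duplicate feature ids {dups}")

    got, want = set(df.columns), set(design.index)
    if got != want:
        extra, miss = sorted(got - want), sorted(want - got)
        raise BundleError(
            f"{name}: sample mismatch with design; "
            f"only in matrix: {extra}; only in design: {miss}"
        )
    df = df[list(design.index)]  # canonical order from the design file

    non_num = df.apply(lambda c: pd.to_numeric(c, errors="coerce"))
    bad = non_num.isna() & df.notna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise BundleError(
            f"{name}: non-numeric value {df.iat[r, c]!r} at "
            f"feature {df.index[r]!r}, sample {df.columns[c]!r}"
        )
    df = non_num
    if df.isna().to_numpy().any():
        if missing == "drop-feature":
            n0 = len(df)
            df = df.dropna(axis=0)
            logger.warning("%s: dropped %d features with missing values", name, n0 - len(df))
        else:
            r, c = np.argwhere(df.isna().to_numpy())[0]
            raise BundleError(
                f"{name}: missing value at feature {df.index[r]!r}, "
                f"sample {df.columns[c]!r} (use missing='drop-feature' to drop)"
            )
    return df.astype(float)


def read_design(path: str | Path, aliases: dict[str, str] | None = None) -> pd.Series:
    """Read the sample -> group design TSV (columns ``sample_id``, ``group``).

    ``aliases`` maps input group labels onto ``case``/``control`` (e.g.
    ``{"GDM": "case", "NGT": "control"}``).
    """
    df = pd.read_csv(path, sep="\t")
    cols = {c.strip().lower(): c for c in df.columns}
    if "sample_id" not in cols or "group" not in cols:
        raise BundleError(f"{path}: design needs 'sample_id' and 'group' columns")
    s = pd.Series(
        df[cols["group"]].astype(str).str.strip().to_numpy(),
        index=df[cols["sample_id"]].astype(str).str.strip(),
        name="group",
    )
    if aliases:
        s = s.replace(aliases)
    bad = sorted(set(s) - set(GROUPS))
    if bad:
        raise BundleError(f"{path}: unknown group labels {bad}; expected {GROUPS}")
    if s.index.duplicated().any():
        raise BundleError(f"{path}: duplicate sample ids in design")
    return s


def read_bundle(
    gene_path: str | Path,
    mirna_path: str | Path,
    lncrna_path: str | Path,
    design_path: str | Path,
    missing: str = "error",
    group_aliases: dict[str, str] | None = None,
) -> ExpressionBundle:
    """Read and cross-validate the three matrices and the design.

    Column order is canonicalised by the design file, so permuting sample
    columns in the input files does not change any downstream statistic.
    Features with zero variance within both groups are flagged in
    ``bundle.zero_variance`` (their correlations/t-tests are degenerate).

    Raises
    ------
    BundleError
        On sample-set mismatch, a group with fewer than 3 samples,
        non-numeric cells, or (by default) missing values.
    """
    design = read_design(design_path, group_aliases)
    for grp in GROUPS:
        n = int((design == grp).sum())
        if n < 3:
            raise BundleError(f"group {grp!r} has {n} samples; >= 3 required")

    mats = {
        "gene": _read_matrix(gene_path, design, missing),
        "miRNA": _read_matrix(mirna_path, design, missing),
        "lncRNA": _read_matrix(lncrna_path, design, missing),
    }
    bundle = ExpressionBundle(
        gene=mats["gene"], mirna=mats["miRNA"], lncrna=mats["lncRNA"], groups=design
    )
    case = design.index[design == "case"]
    ctrl = design.index[design == "control"]
    for kind, m in mats.items():
        flat = m.loc[
            (m[case].var(axis=1, ddof=1) == 0) & (m[ctrl].var(axis=1, ddof=1) == 0)
        ].index
        if len(flat):
            bundle.zero_variance[kind] = list(flat)
            logger.warning(
                "%s: %d features with zero variance in both groups", kind, len(flat)
            )
    return bundle


def write_bundle(
    bundle: ExpressionBundle,
    gene_path: str | Path,
    mirna_path: str | Path,
    lncrna_path: str | Path,
    design_path: str | Path,
    float_format: str = "%.10g",
) -> None:
    """Write a bundle back to the TSV formats ``read_bundle`` consumes."""
    for df, path in (
        (bundle.gene, gene_path),
        (bundle.mirna, mirna_path),
        (bundle.lncrna, lncrna_path),
    ):
        out = df.copy()
        out.index.name = "feature_id"
        out.to_csv(path, sep="\t", float_format=float_format)
    design = bundle.groups.rename("group").rename_axis("sample_id")
    design.to_frame().to_csv(design_path, sep="\t")
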