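"""Per-FFL dysregulation scoring: the package's core statistic.

For each lnc-FFL triplet (gene g, miRNA m, lncRNA l) scored against a
case/control expression bundle:

* ``CS_dif  = P_gene * P_miRNA * P_lncRNA`` — product of the two-sided
  Student t-test p-values of the three molecules (smaller = stronger joint
  differential expression);
* ``CS_PCC = |(r_case_lm - r_ctrl_lm) * (r_case_lg - r_ctrl_lg) *
  (r_case_mg - r_ctrl_mg)|`` — absolute product of the case-minus-control
  Pearson-correlation differences on the three motif edges (larger =
  stronger co-expression rewiring).

FFLs are ranked on each score (CS_dif ascending, CS_PCC descending, average
ranks on ties) and the final comprehensive score is the mean of the two
ranks — lower means more dysregulated.  Significance comes from sample-label
permutations: one shared shuffle of the group labels is applied to all three
matrices per iteration (the samples are the same subjects in every layer),
the whole pipeline is recomputed, and the empirical p-value uses the add-one
estimator p = (1 + #{perm final <= observed final}) / (B + 1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .expression import ExpressionBundle
from .network import LncFFL

logger = logging.getLogger(__name__)

SCORE_COLUMNS = [
    "gene", "miRNA", "lncRNA",
    "p_gene", "p_miRNA", "p_lncRNA", "cs_dif",
    "r_case_lnc_mir", "r_ctrl_lnc_mir",
    "r_case_lnc_gene", "r_ctrl_lnc_gene",
    "r_case_mir_gene", "r_ctrl_mir_gene",
    "cs_pcc", "rank_dif", "rank_pcc", "final_score",
    "perm_p", "dysregulated",
    "pattern_lnc_mir", "pattern_lnc_gene", "pattern_mir_gene",
]


@dataclass(frozen=True)
class EdgeCorrelations:
    """Within-group Pearson correlations on the three motif edges."""

    case_lnc_mir: float
    case_lnc_gene: float
    case_mir_gene: float
    ctrl_lnc_mir: float
    ctrl_lnc_gene: float
    ctrl_mir_gene: float

    def deltas(self) -> tuple[float, float, float]:
        return (
            self.case_lnc_mir - self.ctrl_lnc_mir,
            self.case_lnc_gene - self.ctrl_lnc_gene,
            self.case_mir_gene - self.ctrl_mir_gene,
        )


# ---------------------------------------------------------------------------
# single-FFL reference operations (scipy-backed)

def _ttest_p(case: np.ndarray, ctrl: np.ndarray, equal_var: bool = True) -> float:
    res = stats.ttest_ind(case, ctrl, equal_var=equal_var)
    p = float(res.pvalue)
    if np.isnan(p):  # zero pooled variance: no evidence of a difference
        return 1.0
    return p


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    if np.std(x) == 0 or np.std(y) == 0:
        logger.warning("undefined correlation (zero variance); using 0")
        return 0.0
    return float(stats.pearsonr(x, y).statistic)


def differential_pvalues(
    bundle: ExpressionBundle, ffl: LncFFL, equal_var: bool = True
) -> tuple[float, float, float]:
    """Two-sided Student t-test p-values for gene, miRNA and lncRNA.

    The equal-variance (pooled) test is the default; ``equal_var=False``
    switches to Welch.  A molecule with zero pooled variance yields p = 1.
    """
    case, ctrl = bundle.case_ids, bundle.control_ids
    out = []
    for mat, feat in (
        (bundle.gene, ffl.gene),
        (bundle.mirna, ffl.mirna),
        (bundle.lncrna, ffl.lncrna),
    ):
        row = mat.loc[feat]
        out.append(_ttest_p(row[case].to_numpy(), row[ctrl].to_numpy(), equal_var))
    return tuple(out)  # type: ignore[return-value]


def edge_correlations(bundle: ExpressionBundle, ffl: LncFFL) -> EdgeCorrelations:
    """Six within-group Pearson correlations (three edges x two groups).

    A correlation involving a zero-variance vector is undefined and mapped
    to 0 with a warning.
    """
    g = bundle.gene.loc[ffl.gene]
    m = bundle.mirna.loc[ffl.mirna]
    l = bundle.lncrna.loc[ffl.lncrna]
    vals = {}
    for tag, ids in (("case", bundle.case_ids), ("ctrl", bundle.control_ids)):
        gv, mv, lv = (v[ids].to_numpy() for v in (g, m, l))
        vals[f"{tag}_lnc_mir"] = _pearson(lv, mv)
        vals[f"{tag}_lnc_gene"] = _pearson(lv, gv)
        vals[f"{tag}_mir_gene"] = _pearson(mv, gv)
    return EdgeCorrelations(**vals)


def composite_scores(
    pvals: Sequence[float], corrs: EdgeCorrelations
) -> tuple[float, float]:
    """(CS_dif, CS_PCC) from three p-values and six edge correlations."""
    p_gene, p_mirna, p_lncrna = pvals
    cs_dif = p_gene * p_mirna * p_lncrna
    d1, d2, d3 = corrs.deltas()
    cs_pcc = abs(d1 * d2 * d3)
    return float(cs_dif), float(cs_pcc)


def classify_pattern(corrs: EdgeCorrelations, tau: float = 0.3) -> dict[str, str]:
    """Label the control -> case correlation transition of each motif edge.

    A correlation r is ``negative`` when r <= -tau, ``positive`` when
    r >= tau and ``none`` otherwise; each edge gets a label such as
    ``"positive->negative"`` (nine possible transitions).
    """
    if not 0 < tau < 1:
        raise ValueError("tau must be in (0, 1)")

    def state(r: float) -> str:
        if r <= -tau:
            return "negative"
        if r >= tau:
            return "positive"
        return "none"

    return {
        "pattern_lnc_mir": f"{state(corrs.ctrl_lnc_mir)}->{state(corrs.case_lnc_mir)}",
        "pattern_lnc_gene": f"{state(corrs.ctrl_lnc_gene)}->{state(corrs.case_lnc_gene)}",
        "pattern_mir_gene": f"{state(corrs.ctrl_mir_gene)}->{state(corrs.case_mir_gene)}",
    }


# ---------------------------------------------------------------------------
# vectorised engine (used for scoring whole networks and permutations)

class _ScoringArrays:
    """Dense array view of a bundle restricted to the FFLs being scored."""

    def __init__(self, bundle: ExpressionBundle, ffls: Sequence[LncFFL]):
        kept, skipped = [], []
        for f in ffls:
            if (
                f.gene in bundle.gene.index
                and f.mirna in bundle.mirna.index
                and f.lncrna in bundle.lncrna.index
            ):
                kept.append(f)
            else:
                skipped.append(f)
        if skipped:
            logger.warning(
                "excluded %d FFLs with molecules absent from the matrices "
                "(first: %s)", len(skipped), skipped[0]
            )
        self.ffls = kept
        self.skipped = skipped
        self.G = bundle.gene.to_numpy(dtype=float)
        self.M = bundle.mirna.to_numpy(dtype=float)
        self.L = bundle.lncrna.to_numpy(dtype=float)
        g_ix = {f: i for i, f in enumerate(bundle.gene.index)}
        m_ix = {f: i for i, f in enumerate(bundle.mirna.index)}
        l_ix = {f: i for i, f in enumerate(bundle.lncrna.index)}
        self.gi = np.array([g_ix[f.gene] for f in kept], dtype=int)
        self.mi = np.array([m_ix[f.mirna] for f in kept], dtype=int)
        self.li = np.array([l_ix[f.lncrna] for f in kept], dtype=int)
        labels = bundle.groups.to_numpy()
        self.case_idx = np.flatnonzero(labels == "case")
        self.ctrl_idx = np.flatnonzero(labels == "control")


def _rows_ttest_p(
    X: np.ndarray, case_idx: np.ndarray, ctrl_idx: np.ndarray, equal_var: bool
) -> np.ndarray:
    """Row-wise two-sided t-test p-values; zero-variance rows give p = 1."""
    a, b = X[:, case_idx], X[:, ctrl_idx]
    n1, n2 = a.shape[1], b.shape[1]
    m1, m2 = a.mean(axis=1), b.mean(axis=1)
    v1, v2 = a.var(axis=1, ddof=1), b.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        if equal_var:
            sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
            se2 = sp2 * (1.0 / n1 + 1.0 / n2)
            df = np.full_like(se2, n1 + n2 - 2)
        else:
            se2 = v1 / n1 + v2 / n2
            df = se2**2 / (
                (v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1)
            )
        t = (m1 - m2) / np.sqrt(se2)
        p = 2.0 * stats.t.sf(np.abs(t), df)
    return np.where(np.isfinite(p), p, 1.0)


def _standardized_rows(X: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Centre rows and scale to unit norm; zero-variance rows become zeros."""
    sub = X[:, idx]
    z = sub - sub.mean(axis=1, keepdims=True)
    norm = np.sqrt((z**2).sum(axis=1, keepdims=True))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(norm > 0, z / norm, 0.0)
    return z


def _compute_raw_scores(
    arr: _ScoringArrays,
    case_idx: np.ndarray,
    ctrl_idx: np.ndarray,
    equal_var: bool = True,
) -> dict[str, np.ndarray]:
    pg = _rows_ttest_p(arr.G, case_idx, ctrl_idx, equal_var)[arr.gi]
    pm = _rows_ttest_p(arr.M, case_idx, ctrl_idx, equal_var)[arr.mi]
    pl = _rows_ttest_p(arr.L, case_idx, ctrl_idx, equal_var)[arr.li]
    out: dict[str, np.ndarray] = {"p_gene": pg, "p_miRNA": pm, "p_lncRNA": pl}
    out["cs_dif"] = pg * pm * pl

    for tag, idx in (("case", case_idx), ("ctrl", ctrl_idx)):
        zg = _standardized_rows(arr.G, idx)
        zm = _standardized_rows(arr.M, idx)
        zl = _standardized_rows(arr.L, idx)
        out[f"r_{tag}_lnc_mir"] = (zl[arr.li] * zm[arr.mi]).sum(axis=1)
        out[f"r_{tag}_lnc_gene"] = (zl[arr.li] * zg[arr.gi]).sum(axis=1)
        out[f"r_{tag}_mir_gene"] = (zm[arr.mi] * zg[arr.gi]).sum(axis=1)
    out["cs_pcc"] = np.abs(
        (out["r_case_lnc_mir"] - out["r_ctrl_lnc_mir"])
        * (out["r_case_lnc_gene"] - out["r_ctrl_lnc_gene"])
        * (out["r_case_mir_gene"] - out["r_ctrl_mir_gene"])
    )
    return out


def _final_scores(cs_dif: np.ndarray, cs_pcc: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    rank_dif = stats.rankdata(cs_dif, method="average")
    rank_pcc = stats.rankdata(-cs_pcc, method="average")
    return rank_dif, rank_pcc, (rank_dif + rank_pcc) / 2.0


def rank_and_combine(scores: pd.DataFrame) -> pd.DataFrame:
    """Fill ``rank_dif``, ``rank_pcc`` and ``final_score`` on a score table.

    CS_dif is ranked ascending (rank 1 = most significant differential
    expression), CS_PCC descending (rank 1 = strongest rewiring); ties take
    average ranks; final_score is the equal-weighted mean of the two ranks.
    """
    if len(scores) < 2:
        raise ValueError("ranking needs at least 2 scored FFLs")
    out = scores.copy()
    rank_dif, rank_pcc, final = _final_scores(
        out["cs_dif"].to_numpy(), out["cs_pcc"].to_numpy()
    )
    out["rank_dif"], out["rank_pcc"], out["final_score"] = rank_dif, rank_pcc, final
    return out


def score_ffls(
    bundle: ExpressionBundle,
    ffls: Sequence[LncFFL],
    tau: float = 0.3,
    equal_var: bool = True,
) -> pd.DataFrame:
    """Score every FFL: p-values, correlations, composites, ranks, patterns.

    FFLs whose molecules are missing from the matrices are excluded with a
    logged reason.  Returns a table with one row per scored FFL; permutation
    columns (``perm_p``, ``dysregulated``) are filled by
    :func:`permutation_test`.
    """
    arr = _ScoringArrays(bundle, ffls)
    if len(arr.ffls) < 2:
        raise ValueError("fewer than 2 scorable FFLs")
    raw = _compute_raw_scores(arr, arr.case_idx, arr.ctrl_idx, equal_var)
    df = pd.DataFrame(
        {
            "gene": [f.gene for f in arr.ffls],
            "miRNA": [f.mirna for f in arr.ffls],
            "lncRNA": [f.lncrna for f in arr.ffls],
            **{k: v for k, v in raw.items()},
        }
    )
    df = rank_and_combine(df)
    for i, row in df.iterrows():
        corrs = EdgeCorrelations(
            case_lnc_mir=row["r_case_lnc_mir"],
            case_lnc_gene=row["r_case_lnc_gene"],
            case_mir_gene=row["r_case_mir_gene"],
            ctrl_lnc_mir=row["r_ctrl_lnc_mir"],
            ctrl_lnc_gene=row["r_ctrl_lnc_gene"],
            ctrl_mir_gene=row["r_ctrl_mir_gene"],
        )
        for k, v in classify_pattern(corrs, tau).items():
            df.loc[i, k] = v
    return df


def permutation_test(
    bundle: ExpressionBundle,
    ffls: Sequence[LncFFL],
    n_permutations: int = 1000,
    seed: int | None = None,
    alpha: float = 0.05,
    tau: float = 0.3,
    equal_var: bool = True,
) -> pd.DataFrame:
    """Score FFLs and attach permutation p-values.

    Per iteration one random permutation of the sample labels is shared by
    the gene, miRNA and lncRNA matrices (the samples are matched subjects;
    permuting layers independently would destroy the cross-layer structure
    the statistic measures), the full scoring pipeline is recomputed, and

        perm_p_i = (1 + #{b: final_score_b(i) <= final_score_obs(i)}) / (B + 1)

    FFLs with ``perm_p < alpha`` are flagged ``dysregulated``.
    """
    if n_permutations < 100:
        raise ValueError("at least 100 permutations are required")
    rng = np.random.default_rng(seed)

    df = score_ffls(bundle, ffls, tau=tau, equal_var=equal_var)
    arr = _ScoringArrays(bundle, ffls)
    obs_final = df["final_score"].to_numpy()

    n = len(bundle.sample_ids)
    n_case = len(arr.case_idx)
    labels = np.zeros(n, dtype=bool)
    labels[arr.case_idx] = True

    count_le = np.zeros(len(obs_final), dtype=int)
    for b in range(n_permutations):
        perm = rng.permutation(n)
        case_b = perm[labels]
        ctrl_b = perm[~labels]
        raw = _compute_raw_scores(arr, case_b, ctrl_b, equal_var)
        _, _, final_b = _final_scores(raw["cs_dif"], raw["cs_pcc"])
        count_le += final_b <= obs_final
        if (b + 1) % 100 == 0:
            logger.info("permutation %d/%d", b + 1, n_permutations)

    df["perm_p"] = (1.0 + count_le) / (n_permutations + 1.0)
    df["dysregulated"] = df["perm_p"] < alpha
    return df[SCORE_COLUMNS]


def dysregulated_ffls(scores: pd.DataFrame) -> list[LncFFL]:
    """FFL triplets flagged dysregulated in a scored table."""
    sub = scores[scores["dysregulated"].astype(bool)]
    return [
        LncFFL(r.gene, r.miRNA, r.lncRNA) for r in sub.itertuples(index=False)
    ]
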