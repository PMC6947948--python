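"""Two-part dysregulation scoring of triplets with a permutation null.

For each triplet the evidence of case/control dysregulation is summarised by
two scores:

* ``score_dif = p_immune * p_inflammation * p_disease`` — the product of the
  three per-gene two-sample t-test p-values (small = coordinated differential
  expression);
* ``score_pcc = |Δ_im-in * Δ_im-dis * Δ_in-dis|`` — the absolute product of
  the three between-group Pearson-correlation differences, case minus
  control (large = correlation rewiring).

The two scores are combined by equal weighting of their ranks: score_dif is
ranked descending in dysregulation (smallest p-product gets the largest rank
value) and score_pcc ascending (largest rewiring gets the largest rank
value); the final score is the mean of the two rank values, so larger final
scores mean stronger dysregulation.  Significance comes from shuffling the
sample labels (group sizes preserved), re-scoring and re-ranking the whole
triplet cohort jointly in each permutation, and comparing each triplet's
observed final score with its own permuted ones using the add-one empirical
p-value (1 + #{permuted >= observed}) / (1 + n_perm).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .types import (
    CASE,
    CONTROL,
    DysregulatedNetwork,
    ExpressionMatrix,
    GeneRoleCatalog,
    Triplet,
    TripletScoreRecord,
)

log = logging.getLogger(__name__)

P_FLOOR = 1e-300  # keeps score_dif away from exact zero


# ---------------------------------------------------------------------------
# elementary statistics
# ---------------------------------------------------------------------------

def _t_pvalues(X: np.ndarray, case: np.ndarray, ctrl: np.ndarray,
               test: str = "student") -> np.ndarray:
    """Two-sided two-sample t-test p-value per row of ``X``.

    ``student`` pools the variance; ``welch`` does not.  Degenerate rows with
    zero variance in both groups get p = 1 when the group means agree and the
    floor value when they differ.
    """
    a = X[:, case]
    b = X[:, ctrl]
    n1, n2 = a.shape[1], b.shape[1]
    if n1 < 2 or n2 < 2:
        raise ValueError("need >=2 samples per group for a t-test")
    m1, m2 = a.mean(axis=1), b.mean(axis=1)
    v1, v2 = a.var(axis=1, ddof=1), b.var(axis=1, ddof=1)
    if test == "student":
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
        se2 = sp2 * (1.0 / n1 + 1.0 / n2)
        df = np.full_like(se2, n1 + n2 - 2)
    elif test == "welch":
        se2 = v1 / n1 + v2 / n2
        with np.errstate(divide="ignore", invalid="ignore"):
            df = se2**2 / (v1**2 / (n1**2 * (n1 - 1)) + v2**2 / (n2**2 * (n2 - 1)))
    else:
        raise ValueError(f"unknown test {test!r}")
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m1 - m2) / np.sqrt(se2)
        p = 2.0 * stats.t.sf(np.abs(t), df)
    degenerate = se2 <= 0
    p = np.where(degenerate & (m1 == m2), 1.0, p)
    p = np.where(degenerate & (m1 != m2), P_FLOOR, p)
    return np.clip(p, P_FLOOR, 1.0)


def gene_pvalue(expr: ExpressionMatrix, gene: str,
                test: str = "student") -> float:
    """Case-vs-control t-test p-value for one gene (two-sided)."""
    if gene not in expr:
        raise KeyError(f"gene {gene!r} not in expression matrix")
    row = expr.data.loc[[gene]].to_numpy()
    return float(_t_pvalues(row, expr.group_columns(CASE),
                            expr.group_columns(CONTROL), test)[0])


def _pair_corrs(X: np.ndarray, cols: np.ndarray,
                pairs: np.ndarray) -> np.ndarray:
    """Pearson correlation per (row_i, row_j) pair over the given columns.

    Rows are z-scored (population SD); a pair involving a constant row gets
    correlation 0.
    """
    G = X[:, cols]
    mu = G.mean(axis=1, keepdims=True)
    sd = G.std(axis=1, keepdims=True)
    const = (sd[:, 0] == 0)
    Z = (G - mu) / np.where(sd == 0, 1.0, sd)
    i, j = pairs[:, 0], pairs[:, 1]
    r = (Z[i] * Z[j]).mean(axis=1)
    bad = const[i] | const[j]
    if bad.any():
        log.warning("%d gene pairs with a constant expression vector; "
                    "their correlation is set to 0", int(bad.sum()))
    r = np.where(bad, 0.0, r)
    return np.clip(r, -1.0, 1.0)


def pair_pcc(expr: ExpressionMatrix, gene_x: str, gene_y: str,
             group: str) -> float:
    """Within-group Pearson correlation between two genes' expression."""
    for g in (gene_x, gene_y):
        if g not in expr:
            raise KeyError(f"gene {g!r} not in expression matrix")
    cols = expr.group_columns(group)
    if len(cols) < 3:
        raise ValueError(f"group {group} has {len(cols)} samples; need >=3")
    X = expr.data.loc[[gene_x, gene_y]].to_numpy()
    return float(_pair_corrs(X, cols, np.array([[0, 1]]))[0])


# ---------------------------------------------------------------------------
# vectorised scoring engine
# ---------------------------------------------------------------------------

@dataclass
class _Engine:
    """Precomputed index structure for scoring many triplets repeatedly
    (used verbatim for the observed labels and for every permutation)."""

    X: np.ndarray                 # unique genes × samples
    gene_idx: np.ndarray          # n_triplets × 3 rows into X
    pair_idx: np.ndarray          # n_pairs × 2 rows into X (unique pairs)
    triplet_pairs: np.ndarray     # n_triplets × 3 rows into pair_idx
    test: str

    def scores(self, case: np.ndarray, ctrl: np.ndarray
               ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray,
                          np.ndarray]:
        p = _t_pvalues(self.X, case, ctrl, self.test)
        r_case = _pair_corrs(self.X, case, self.pair_idx)
        r_ctrl = _pair_corrs(self.X, ctrl, self.pair_idx)
        p3 = p[self.gene_idx]                       # T × 3
        score_dif = p3.prod(axis=1)
        delta = (r_case - r_ctrl)[self.triplet_pairs]  # T × 3
        score_pcc = np.abs(delta.prod(axis=1))
        return score_dif, score_pcc, p3, r_case[self.triplet_pairs], \
            r_ctrl[self.triplet_pairs]


def _build_engine(expr: ExpressionMatrix, triplets: list[Triplet],
                  test: str) -> tuple[_Engine, list[Triplet]]:
    complete = expr.data.notna().all(axis=1)
    usable = set(expr.data.index[complete])
    n_nan = int((~complete).sum())
    if n_nan:
        log.warning("%d genes with missing values excluded from scoring", n_nan)
    kept = [t for t in triplets if all(g in usable for g in t.genes)]
    dropped = len(triplets) - len(kept)
    if dropped:
        log.warning("%d triplets dropped (gene absent or incomplete)", dropped)
    if not kept:
        raise ValueError("no triplet has all three genes in the matrix")
    genes = sorted({g for t in kept for g in t.genes})
    gpos = {g: i for i, g in enumerate(genes)}
    gene_idx = np.array([[gpos[g] for g in t.genes] for t in kept])
    pair_set = sorted({tuple(sorted((gpos[a], gpos[b])))
                       for t in kept for a, b in t.pairs})
    ppos = {p: i for i, p in enumerate(pair_set)}
    triplet_pairs = np.array([
        [ppos[tuple(sorted((gpos[a], gpos[b])))] for a, b in t.pairs]
        for t in kept
    ])
    X = expr.data.loc[genes].to_numpy()
    return _Engine(X, gene_idx, np.array(pair_set), triplet_pairs, test), kept


def score_triplets(expr: ExpressionMatrix, triplets: list[Triplet],
                   test: str = "student") -> list[TripletScoreRecord]:
    """Fill score_dif / score_pcc (and their ingredients) per triplet.

    Triplets with a gene absent from the matrix, or with missing values in
    its row, are dropped with a logged warning.
    """
    engine, kept = _build_engine(expr, triplets, test)
    case, ctrl = expr.group_columns(CASE), expr.group_columns(CONTROL)
    for cols, name in ((case, CASE), (ctrl, CONTROL)):
        if len(cols) < 3:
            raise ValueError(f"group {name} has {len(cols)} samples; need >=3")
    score_dif, score_pcc, p3, rc, rn = engine.scores(case, ctrl)
    records = []
    for i, t in enumerate(kept):
        records.append(TripletScoreRecord(
            triplet=t,
            p_immune=float(p3[i, 0]), p_inflammation=float(p3[i, 1]),
            p_disease=float(p3[i, 2]),
            pcc_case_im_in=float(rc[i, 0]), pcc_case_im_d=float(rc[i, 1]),
            pcc_case_in_d=float(rc[i, 2]),
            pcc_ctrl_im_in=float(rn[i, 0]), pcc_ctrl_im_d=float(rn[i, 1]),
            pcc_ctrl_in_d=float(rn[i, 2]),
            score_dif=float(score_dif[i]), score_pcc=float(score_pcc[i]),
        ))
    return records


def _final_scores(score_dif: np.ndarray, score_pcc: np.ndarray
                  ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    rank_dif = stats.rankdata(-score_dif)   # smallest p-product → largest rank
    rank_pcc = stats.rankdata(score_pcc)    # largest rewiring → largest rank
    return rank_dif, rank_pcc, (rank_dif + rank_pcc) / 2.0


def _ranks_against(reference_sorted: np.ndarray, values: np.ndarray,
                   descending: bool) -> np.ndarray:
    """Average-rank of each value measured on a fixed sorted reference scale.

    With ``descending=False`` larger values get larger ranks (ascending
    orientation); with ``descending=True`` smaller values get larger ranks.
    A value tied with reference entries receives the mean of the positions
    it straddles, matching the average-rank convention of
    :func:`scipy.stats.rankdata` when the value belongs to the reference.
    """
    lo = np.searchsorted(reference_sorted, values, side="left")
    hi = np.searchsorted(reference_sorted, values, side="right")
    below = (lo + hi) / 2.0  # reference entries strictly below, + half the ties
    rank_asc = below + 0.5
    if descending:
        return len(reference_sorted) + 1 - rank_asc
    return rank_asc


def combine_ranks(records: list[TripletScoreRecord]
                  ) -> list[TripletScoreRecord]:
    """Equally weighted rank combination; ties get average (fractional) ranks.

    Returns the same record list with rank_dif / rank_pcc / final_score set.
    """
    if not records:
        raise ValueError("no records to rank")
    score_dif = np.array([r.score_dif for r in records])
    score_pcc = np.array([r.score_pcc for r in records])
    rank_dif, rank_pcc, final = _final_scores(score_dif, score_pcc)
    for r, rd, rp, f in zip(records, rank_dif, rank_pcc, final):
        r.rank_dif, r.rank_pcc, r.final_score = float(rd), float(rp), float(f)
    return records


def permutation_pvalues(expr: ExpressionMatrix, triplets: list[Triplet],
                        n_perm: int = 1000, seed: int | None = None,
                        test: str = "student",
                        null_reference: str = "observed"
                        ) -> list[TripletScoreRecord]:
    """Score, rank and permutation-test a triplet cohort.

    Each permutation shuffles the sample labels (group sizes preserved) and
    re-scores every triplet; a triplet's permutation p-value is the add-one
    tail frequency of its permuted final scores at or above its observed
    one.  ``null_reference`` controls the scale on which a permuted score
    becomes a final (rank) score:

    * ``"observed"`` (default): the permuted score_dif / score_pcc are
      ranked against the *observed* cohort's score distributions, so the
      permuted final score answers "where would a label-shuffled version of
      this triplet land on the real ranking?".  This keeps power when a
      sizeable fraction of the cohort is genuinely dysregulated.
    * ``"cohort"``: the permuted cohort is re-ranked jointly against itself.
      Marginally the permuted final score is then a uniform draw over the
      rank range whenever triplets are exchangeable, which caps how many
      triplets can ever reach small p-values.

    Fully reproducible under ``seed``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if null_reference not in ("observed", "cohort"):
        raise ValueError(f"unknown null_reference {null_reference!r}")
    engine, kept = _build_engine(expr, triplets, test)
    case = expr.group_columns(CASE)
    ctrl = expr.group_columns(CONTROL)
    n_case = len(case)
    all_cols = np.concatenate([case, ctrl])

    score_dif, score_pcc, p3, rc, rn = engine.scores(case, ctrl)
    rank_dif, rank_pcc, observed = _final_scores(score_dif, score_pcc)
    dif_sorted = np.sort(score_dif)
    pcc_sorted = np.sort(score_pcc)

    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(kept), dtype=int)
    for _ in range(n_perm):
        perm = rng.permutation(all_cols)
        sd, sp, *_ = engine.scores(perm[:n_case], perm[n_case:])
        if null_reference == "cohort":
            _, _, perm_final = _final_scores(sd, sp)
        else:
            rd = _ranks_against(dif_sorted, sd, descending=True)
            rp = _ranks_against(pcc_sorted, sp, descending=False)
            perm_final = (rd + rp) / 2.0
        exceed += perm_final >= observed
    perm_p = (1.0 + exceed) / (1.0 + n_perm)

    records = []
    for i, t in enumerate(kept):
        records.append(TripletScoreRecord(
            triplet=t,
            p_immune=float(p3[i, 0]), p_inflammation=float(p3[i, 1]),
            p_disease=float(p3[i, 2]),
            pcc_case_im_in=float(rc[i, 0]), pcc_case_im_d=float(rc[i, 1]),
            pcc_case_in_d=float(rc[i, 2]),
            pcc_ctrl_im_in=float(rn[i, 0]), pcc_ctrl_im_d=float(rn[i, 1]),
            pcc_ctrl_in_d=float(rn[i, 2]),
            score_dif=float(score_dif[i]), score_pcc=float(score_pcc[i]),
            rank_dif=float(rank_dif[i]), rank_pcc=float(rank_pcc[i]),
            final_score=float(observed[i]), perm_p=float(perm_p[i]),
        ))
    return records


def select_dysregulated(records: list[TripletScoreRecord],
                        catalog: GeneRoleCatalog,
                        alpha: float = 0.05) -> DysregulatedNetwork:
    """Keep records with perm_p strictly below ``alpha`` (no multiplicity
    correction) and assemble their triangles into a subnetwork."""
    significant = [r for r in records if r.perm_p < alpha]
    edges: set[frozenset[str]] = set()
    nodes: dict[str, str] = {}
    for r in significant:
        edges.update(r.triplet.edges)
        for g in r.triplet.genes:
            nodes.setdefault(g, catalog.category_of(g))
    return DysregulatedNetwork(
        triplets=[r.triplet for r in significant],
        nodes=nodes, edges=edges, records=significant, alpha=alpha,
    )


def rank_concordance(records: list[TripletScoreRecord],
                     selected: list[TripletScoreRecord]) -> float:
    """Percentage of significant triplets found within the top |selected|
    positions of the global final-score ranking.

    100% means the permutation-significant set coincides with the head of
    the ranking; lower values mean significance and rank order disagree.
    """
    if not selected:
        raise ValueError("empty selection")
    order = sorted(records,
                   key=lambda r: (-r.final_score, r.triplet))
    k = len(selected)
    top = {r.triplet for r in order[:k]}
    n_in_top = sum(1 for r in selected if r.triplet in top)
    return 100.0 * n_in_top / k
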