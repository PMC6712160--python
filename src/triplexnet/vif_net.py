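"""Streamwise VIF regression and integrative network assembly.

For every target transcript the expression of all other transcripts (any
biotype) is streamed as candidate regulators, approximating the l0-penalized
least-squares objective

    argmin_beta ||y - X beta||^2 + lambda0 * sum_i 1{beta_i != 0}

with a greedy one-pass procedure: candidates are ordered by marginal
correlation with the target on a pre-sampled subset, each is tested against
the current residual with a t-statistic whose variance is corrected by the
candidate's variance inflation factor (VIF, estimated on the same subset),
and acceptance is governed by an alpha-investing wealth sequence.  The
sparsity penalty lambda0 is expressed through that significance budget
(initial wealth ``w0``, ``payout`` earned per acceptance) rather than as an
explicit multiplier.  Models are scored by adjusted R-squared, and only
models with adjusted R-squared strictly greater than the threshold
contribute edges to the combined, undirected, biotype-labelled network.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .containers import ExpressionMatrix

logger = logging.getLogger(__name__)


@dataclass
class VifParams:
    """Tuning knobs of the streamwise selector.

    w0, payout
        Alpha-investing budget: wealth starts at ``w0``; the j-th test spends
        ``alpha_j = w_j / (2 j)``; an acceptance pays back ``payout``.
    subsample_size
        Rows pre-sampled once per target for the marginal screen and for the
        VIF estimates (capped at n).
    max_regulators
        Hard cap on the selected-set size.
    r2_threshold
        Models are kept iff adjusted R-squared is strictly greater than this.
    removal_pass
        Whether a single backward-elimination sweep follows the forward pass.
    """

    w0: float = 0.05
    payout: float = 0.05
    subsample_size: int = 200
    max_regulators: int = 50
    r2_threshold: float = 0.8
    removal_pass: bool = True

    def validate(self) -> None:
        if not 0.0 < self.w0 <= 1.0:
            raise ValueError("w0 must lie in (0, 1]")
        if self.payout <= 0:
            raise ValueError("payout must be > 0")
        if self.subsample_size < 10:
            raise ValueError("subsample_size must be >= 10")
        if not 0.0 < self.r2_threshold < 1.0:
            raise ValueError("r2_threshold must lie in (0, 1)")
        if self.max_regulators < 1:
            raise ValueError("max_regulators must be >= 1")


@dataclass
class RegressionModel:
    """One fitted target: its selected regulators and goodness-of-fit."""

    target_id: str
    regulators: list[str]
    coefficients: list[float]
    n: int
    r2: float
    adj_r2: float

    @property
    def p_selected(self) -> int:
        return len(self.regulators)


def adjusted_r2(r2: float, n: int, p: int) -> float:
    """1 - (1 - r2) (n - 1) / (n - p - 1), with p the number of SELECTED
    regulators (not the size of the candidate pool)."""
    if n <= p + 1:
        raise ValueError(f"adjusted R2 undefined: n={n} <= p+1={p + 1}")
    if not 0.0 <= r2 <= 1.0:
        raise ValueError("r2 must lie in [0, 1]")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


def _subsample_rows(n: int, size: int, seed: int) -> np.ndarray:
    if n <= size:
        return np.arange(n)
    rng = np.random.default_rng(seed)
    return np.sort(rng.choice(n, size=size, replace=False))


def marginal_screen(y: pd.Series, candidates: ExpressionMatrix, params: VifParams,
                    seed: int) -> list[str]:
    """All candidate ids sorted by decreasing |Pearson r| with the target on a
    seeded subsample; ties broken by lexicographically smaller id."""
    params.validate()
    yv = y.to_numpy(dtype=float)
    if yv.std() == 0:
        raise ValueError(f"constant target {y.name!r}: drop before screening")
    X = candidates.values.to_numpy(dtype=float).T  # samples x p
    idx = _subsample_rows(len(yv), params.subsample_size, seed)
    ys = yv[idx] - yv[idx].mean()
    Xs = X[idx] - X[idx].mean(axis=0)
    xnorm = np.sqrt((Xs**2).sum(axis=0))
    ynorm = np.sqrt((ys**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Xs.T @ ys) / (xnorm * ynorm)
    absr = np.abs(np.nan_to_num(r, nan=0.0))
    ids = np.asarray(candidates.transcript_ids, dtype=object)
    order = np.lexsort((ids, -absr))  # primary: |r| desc; secondary: id asc
    return [str(t) for t in ids[order]]


def _ols(Xc: np.ndarray, yc: np.ndarray) -> tuple[np.ndarray, np.ndarray, float, int]:
    """Least squares on centred data; returns (beta, residual, rss, rank)."""
    if Xc.shape[1] == 0:
        return np.zeros(0), yc.copy(), float(yc @ yc), 0
    beta, _, rank, _ = np.linalg.lstsq(Xc, yc, rcond=None)
    resid = yc - Xc @ beta
    return beta, resid, float(resid @ resid), int(rank)


def vif_streamwise_fit(y: pd.Series, candidates: ExpressionMatrix, params: VifParams,
                       seed: int) -> RegressionModel:
    """One streamwise forward pass with alpha-investing and VIF-corrected
    t-tests, optionally followed by a backward-elimination sweep.

    For each candidate in marginal-screen order the t-statistic of the
    candidate against the current residual is computed.  Because the
    residual is orthogonal to the selected set, the marginal coefficient is
    attenuated by (1 - rho^2) and its naive standard error overestimates
    the true sampling error by the candidate's variance inflation factor
    VIF = 1/(1 - rho^2); the statistic is therefore corrected to
    t / sqrt(1 - rho^2), with rho^2 (the R-squared of the candidate on the
    selected set) estimated on the pre-sampled subset.  The candidate
    enters iff the corrected two-sided p-value beats the current
    alpha-investing level.  The final coefficients are the OLS fit of the
    selected set on the full data.
    """
    params.validate()
    target_id = str(y.name)
    yv = y.to_numpy(dtype=float)
    n = len(yv)
    if n < 10:
        raise ValueError("need at least 10 samples")
    if yv.std() == 0:
        raise ValueError(f"constant target {target_id!r}")

    order = marginal_screen(y, candidates, params, seed)
    col = {tid: i for i, tid in enumerate(candidates.transcript_ids)}
    X = candidates.values.to_numpy(dtype=float).T  # samples x p
    Xc = X - X.mean(axis=0)
    yc = yv - yv.mean()
    col_ss = (Xc**2).sum(axis=0)
    sub = _subsample_rows(n, params.subsample_size, seed)

    selected: list[str] = []
    sel_idx: list[int] = []
    resid = yc.copy()
    rss = float(yc @ yc)
    dots = Xc.T @ resid
    wealth = params.w0
    last_alpha = params.w0 / 2.0
    # orthonormal basis of the selected columns on the subsample, for cheap
    # per-candidate rho^2 (VIF) estimates
    Xsub = Xc[sub] - Xc[sub].mean(axis=0)
    sub_ss = (Xsub**2).sum(axis=0)
    Q = np.empty((len(sub), 0))

    tss_y = float(yc @ yc)
    for j, tid in enumerate(order, start=1):
        if len(selected) >= params.max_regulators or n <= len(selected) + 2:
            break
        if rss <= 1e-12 * tss_y:  # perfect fit: nothing left to explain
            break
        alpha = wealth / (2.0 * j)
        last_alpha = alpha
        k = col[tid]
        df = n - len(selected) - 2
        if col_ss[k] <= 0:  # constant candidate: untestable
            wealth -= alpha / (1.0 - alpha)
            continue
        gamma = dots[k] / col_ss[k]
        rss_new = max(rss - gamma * gamma * col_ss[k], 0.0)
        rho2 = 0.0
        if Q.shape[1] and sub_ss[k] > 0:
            proj = Q.T @ Xsub[:, k]
            rho2 = min(max(float(proj @ proj) / sub_ss[k], 0.0), 1.0)
        if rho2 >= 1.0 - 1e-10:
            logger.warning("%s: candidate %s collinear with selected set; dropped",
                           target_id, tid)
            continue
        if rss_new <= 1e-12 * max(tss_y, 1.0):
            t_corr = np.inf if gamma * gamma * col_ss[k] > 1e-12 * tss_y else 0.0
        else:
            sigma2 = rss_new / df
            t_corr = gamma / np.sqrt(sigma2 / col_ss[k]) / np.sqrt(1.0 - rho2)
        p_corr = 2.0 * stats.t.sf(abs(t_corr), df) if np.isfinite(t_corr) else 0.0
        wealth -= alpha / (1.0 - alpha)  # every test costs its bid
        if p_corr < alpha:
            trial = sel_idx + [k]
            beta, new_resid, new_rss, rank = _ols(Xc[:, trial], yc)
            if rank < len(trial):
                logger.warning("%s: candidate %s collinear with selected set; dropped",
                               target_id, tid)
                continue
            selected.append(tid)
            sel_idx.append(k)
            resid, rss = new_resid, new_rss
            dots = Xc.T @ resid
            wealth += params.payout
            # extend the subsample basis with the accepted column
            q = Xsub[:, k] - Q @ (Q.T @ Xsub[:, k])
            norm = np.linalg.norm(q)
            if norm > 1e-12:
                Q = np.column_stack([Q, q / norm])

    if params.removal_pass:
        while selected:
            Z = Xc[:, sel_idx]
            beta, r_, rss_, rank = _ols(Z, yc)
            df = n - len(selected) - 1
            if df <= 0:
                break
            sigma2 = rss_ / df
            try:
                cov = sigma2 * np.linalg.inv(Z.T @ Z)
            except np.linalg.LinAlgError:
                cov = sigma2 * np.linalg.pinv(Z.T @ Z)
            se = np.sqrt(np.maximum(np.diag(cov), 1e-300))
            pvals = 2.0 * stats.t.sf(np.abs(beta / se), df)
            worst = int(np.argmax(pvals))
            if pvals[worst] > last_alpha:
                selected.pop(worst)
                sel_idx.pop(worst)
            else:
                break

    beta, resid, rss, _ = _ols(Xc[:, sel_idx], yc)
    tss = float(yc @ yc)
    r2 = 1.0 - rss / tss if tss > 0 else 0.0
    r2 = min(max(r2, 0.0), 1.0)
    return RegressionModel(
        target_id=target_id,
        regulators=list(selected),
        coefficients=[float(b) for b in beta],
        n=n,
        r2=r2,
        adj_r2=adjusted_r2(r2, n, len(selected)),
    )


def target_seed(global_seed: int, target_id: str) -> int:
    """Deterministic per-target seed so serial and parallel runs agree."""
    return zlib.crc32(f"{global_seed}:{target_id}".encode()) & 0x7FFFFFFF


def fit_all_targets(m: ExpressionMatrix, params: VifParams, seed: int,
                    progress_every: int = 500) -> list[RegressionModel]:
    """Fit one streamwise model per transcript, using all other transcripts
    (any biotype) as candidates.  Per-target failures are logged and skipped."""
    if m.n_transcripts == 0:
        raise ValueError("empty expression matrix")
    models: list[RegressionModel] = []
    for i, tid in enumerate(m.transcript_ids):
        candidates = ExpressionMatrix(
            m.values.drop(index=tid), m.biotypes.drop(index=tid))
        try:
            models.append(vif_streamwise_fit(
                m.row(tid), candidates, params, target_seed(seed, tid)))
        except (ValueError, np.linalg.LinAlgError) as exc:
            logger.warning("target %s skipped: %s", tid, exc)
        if progress_every and (i + 1) % progress_every == 0:
            logger.info("fitted %d/%d targets", i + 1, m.n_transcripts)
    return models


# ---------------------------------------------------------------------------
# network assembly
# ---------------------------------------------------------------------------


@dataclass
class TypedNetwork:
    """Undirected association network whose nodes carry a biotype and whose
    edges carry the best supporting adjusted R-squared."""

    graph: nx.Graph = field(default_factory=nx.Graph)

    def add_edge(self, a: str, b: str, support: float, biotype_a: str, biotype_b: str) -> None:
        if a == b:
            raise ValueError("self-loops are not allowed")
        self.graph.add_node(a, biotype=biotype_a)
        self.graph.add_node(b, biotype=biotype_b)
        prev = self.graph.edges.get((a, b), {}).get("support", -np.inf)
        self.graph.add_edge(a, b, support=max(prev, support))

    def biotype(self, node: str) -> str:
        return self.graph.nodes[node]["biotype"]

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edge_set(self) -> set[tuple[str, str]]:
        return {tuple(sorted(e)) for e in self.graph.edges}

    def biotype_counts(self) -> dict[str, int]:
        from .containers import BIOTYPES

        counts = {bt: 0 for bt in BIOTYPES}
        for _, bt in self.graph.nodes(data="biotype"):
            counts[bt] = counts.get(bt, 0) + 1
        return counts

    def write_edge_tsv(self, path: str | Path) -> None:
        rows = [
            {"node_a": a, "node_b": b, "support_adj_r2": d["support"]}
            for a, b, d in sorted(self.graph.edges(data=True), key=lambda e: tuple(sorted(e[:2])))
        ]
        pd.DataFrame(rows, columns=["node_a", "node_b", "support_adj_r2"]).to_csv(
            path, sep="\t", index=False)

    def write_graphml(self, path: str | Path) -> None:
        nx.write_graphml(self.graph, path)

    @classmethod
    def from_edge_tsv(cls, path: str | Path, biotypes: pd.Series) -> "TypedNetwork":
        df = pd.read_csv(path, sep="\t")
        net = cls()
        for a, b, s in df[["node_a", "node_b", "support_adj_r2"]].itertuples(index=False):
            net.add_edge(str(a), str(b), float(s), str(biotypes.loc[a]), str(biotypes.loc[b]))
        return net


def build_network(models: Sequence[RegressionModel], m: ExpressionMatrix,
                  params: Optional[VifParams] = None) -> TypedNetwork:
    """Combine the kept models (adjusted R-squared strictly above threshold)
    into one undirected network.  Each kept model contributes an edge between
    its target and every selected regulator; duplicate edges keep the maximum
    supporting adjusted R-squared.  Isolated transcripts never enter the node
    set.  The result is invariant to the ordering of ``models``."""
    params = params or VifParams()
    threshold = params.r2_threshold
    net = TypedNetwork()
    bt = m.biotypes
    for model in models:
        if not model.adj_r2 > threshold:  # strict: exactly-at-threshold excluded
            continue
        for reg in model.regulators:
            net.add_edge(model.target_id, reg, model.adj_r2,
                         str(bt.loc[model.target_id]), str(bt.loc[reg]))
    return net
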