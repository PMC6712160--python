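"""Biotype-constrained clique enumeration on the integrative network.

A triplet is a triangle whose three nodes are exactly one mRNA, one lncRNA
and one miRNA; a four-clique is a K4 whose biotype multiset covers all three
biotypes.  Enumeration runs over node-ordered adjacency intersections
(every triangle/K4 is produced exactly once), not via maximal-clique
listing: the analysis needs all small cliques, maximal or not.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .vif_net import TypedNetwork

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Triplet:
    """A typed 3-clique; slots are typed, so (mrna, lncrna, mirna) order is fixed."""

    mrna_id: str
    lncrna_id: str
    mirna_id: str
    edge_supports: tuple[float, float, float] = (float("nan"),) * 3
    # supports ordered: (mrna-lncrna, mrna-mirna, lncrna-mirna)

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.mrna_id, self.lncrna_id, self.mirna_id)

    @property
    def members(self) -> frozenset[str]:
        return frozenset(self.key)


@dataclass(frozen=True)
class FourClique:
    """A K4 containing at least one node of each biotype."""

    member_ids: tuple[str, str, str, str]
    biotype_multiset: tuple[tuple[str, int], ...]

    @property
    def members(self) -> frozenset[str]:
        return frozenset(self.member_ids)


def _ordered_adjacency(net: TypedNetwork) -> tuple[list[str], dict[str, set[str]]]:
    nodes = sorted(net.graph.nodes)
    adj = {u: set(net.graph.neighbors(u)) for u in nodes}
    return nodes, adj


def _triangles(net: TypedNetwork) -> Iterable[tuple[str, str, str]]:
    """Every triangle exactly once, as (u, v, w) with u < v < w."""
    _, adj = _ordered_adjacency(net)
    for u in sorted(adj):
        for v in sorted(n for n in adj[u] if n > u):
            for w in sorted(adj[u] & adj[v]):
                if w > v:
                    yield u, v, w


def enumerate_typed_triplets(net: TypedNetwork) -> list[Triplet]:
    """All triangles with biotypes exactly {mRNA, lncRNA, miRNA}, sorted by
    (mrna_id, lncrna_id, mirna_id)."""
    out: list[Triplet] = []
    for tri in _triangles(net):
        slot = {net.biotype(n): n for n in tri}
        if len(slot) != 3:
            continue
        m, l, r = slot["mRNA"], slot["lncRNA"], slot["miRNA"]
        sup = (
            net.graph.edges[m, l].get("support", float("nan")),
            net.graph.edges[m, r].get("support", float("nan")),
            net.graph.edges[l, r].get("support", float("nan")),
        )
        out.append(Triplet(m, l, r, sup))
    out.sort(key=lambda t: t.key)
    return out


def enumerate_typed_fourcliques(net: TypedNetwork) -> list[FourClique]:
    """All K4 subgraphs containing at least one node of each biotype, sorted."""
    _, adj = _ordered_adjacency(net)
    out: list[FourClique] = []
    for u, v, w in _triangles(net):
        for x in sorted(adj[u] & adj[v] & adj[w]):
            if x <= w:
                continue
            members = (u, v, w, x)
            bts = [net.biotype(n) for n in members]
            if {"mRNA", "lncRNA", "miRNA"} <= set(bts):
                multiset = tuple(sorted((bt, bts.count(bt)) for bt in set(bts)))
                out.append(FourClique(members, multiset))
    out.sort(key=lambda f: f.member_ids)
    return out


def contained_triplets(fc: FourClique, triplets: Sequence[Triplet]) -> list[Triplet]:
    """The typed triplets whose three members all lie inside the four-clique.
    Every valid four-clique contains at least one (pick one node per biotype:
    all pairs are clique edges)."""
    members = fc.members
    return [t for t in triplets if t.members <= members]


def overlap_cliques(a: Sequence[Triplet], b: Sequence[Triplet]) -> list[Triplet]:
    """Triplets whose typed (mrna, lncrna, mirna) keys appear in both lists.

    Matching is on identifier strings; slots are typed, so no within-slot
    permutation is considered.  An empty overlap between two large inputs is
    logged as a possible identifier-namespace mismatch."""
    keys_b = {t.key for t in b}
    common = [t for t in a if t.key in keys_b]
    if not common and len(a) > 50 and len(b) > 50:
        logger.warning(
            "no overlapping triplets between lists of size %d and %d; "
            "check that both use the same identifier namespace", len(a), len(b))
    return common


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def triplets_to_frame(triplets: Sequence[Triplet]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "mrna_id": t.mrna_id,
                "lncrna_id": t.lncrna_id,
                "mirna_id": t.mirna_id,
                "support_mrna_lncrna": t.edge_supports[0],
                "support_mrna_mirna": t.edge_supports[1],
                "support_lncrna_mirna": t.edge_supports[2],
            }
            for t in triplets
        ],
        columns=[
            "mrna_id", "lncrna_id", "mirna_id",
            "support_mrna_lncrna", "support_mrna_mirna", "support_lncrna_mirna",
        ],
    )


def write_triplets_tsv(triplets: Sequence[Triplet], path: str | Path) -> None:
    triplets_to_frame(triplets).to_csv(path, sep="\t", index=False)


def read_triplets_tsv(path: str | Path) -> list[Triplet]:
    df = pd.read_csv(path, sep="\t")
    return [
        Triplet(
            str(r.mrna_id), str(r.lncrna_id), str(r.mirna_id),
            (float(r.support_mrna_lncrna), float(r.support_mrna_mirna),
             float(r.support_lncrna_mirna)),
        )
        for r in df.itertuples(index=False)
    ]


def write_fourcliques_tsv(cliques: Sequence[FourClique], path: str | Path) -> None:
    rows = [
        {
            "member_1": f.member_ids[0],
            "member_2": f.member_ids[1],
            "member_3": f.member_ids[2],
            "member_4": f.member_ids[3],
            "biotypes": ";".join(f"{bt}:{c}" for bt, c in f.biotype_multiset),
        }
        for f in cliques
    ]
    pd.DataFrame(rows, columns=["member_1", "member_2", "member_3", "member_4",
                                "biotypes"]).to_csv(path, sep="\t", index=False)
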