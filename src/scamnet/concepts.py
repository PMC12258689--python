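"""Global explanations: cluster masked-subgraph embeddings into recurring concepts.

For every record and channel, nodes whose importance clears a threshold are
grouped into connected components; each component's embedding is the
importance-weighted mean of that channel's final-layer node embeddings.
Per channel, embeddings are reduced to 8 dimensions (PCA) and clustered with
a density-based method (DBSCAN) that leaves noise unassigned, so the number
of concepts is data-driven rather than preset. Each cluster is summarized by
representative molecules near its centroid and a consensus substructure
(maximum common substructure of the representatives, with a fragment-
frequency fallback for pathological clusters).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from collections import Counter

import numpy as np
from rdkit import Chem
from rdkit.Chem import rdFMCS
from sklearn.cluster import DBSCAN
from sklearn.decomposition import PCA

from .chemio import LabeledRecord, to_graph
from .model import ModelParameters, forward_batch, make_batch

__all__ = [
    "SubgraphEmbedding",
    "ConceptCluster",
    "extract_subgraphs",
    "cluster_concepts",
    "concept_report",
]


@dataclass
class SubgraphEmbedding:
    """A thresholded high-importance connected component and its embedding."""

    source_id: str
    source_smiles: str
    channel: int
    atom_indices: tuple[int, ...]
    vector: np.ndarray


@dataclass
class ConceptCluster:
    """One recurring structural concept within one explanation channel."""

    cluster_id: int
    channel: int
    members: list[SubgraphEmbedding]
    centroid: np.ndarray
    representatives: list[tuple[str, str]] = field(default_factory=list)  # (id, smiles)

    @property
    def size(self) -> int:
        return len(self.members)


def _connected_components(selected: np.ndarray, bonds: list[tuple[int, int]]) -> list[list[int]]:
    """Components of the subgraph induced by `selected` node flags."""
    adj: dict[int, list[int]] = {i: [] for i in np.flatnonzero(selected)}
    for i, j in bonds:
        if selected[i] and selected[j]:
            adj[i].append(j)
            adj[j].append(i)
    seen: set[int] = set()
    comps = []
    for start in adj:
        if start in seen:
            continue
        comp, stack = [], [start]
        seen.add(start)
        while stack:
            u = stack.pop()
            comp.append(u)
            for v in adj[u]:
                if v not in seen:
                    seen.add(v)
                    stack.append(v)
        comps.append(sorted(comp))
    return comps


def extract_subgraphs(
    params: ModelParameters,
    records: list[LabeledRecord],
    threshold: float = 0.5,
) -> list[SubgraphEmbedding]:
    """Importance-thresholded connected components with weighted-mean embeddings.

    Components smaller than 2 atoms are discarded; a record contributing no
    component is skipped.
    """
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must be in (0, 1)")
    out: list[SubgraphEmbedding] = []
    for rec in records:
        graph = to_graph(rec.molecule, params.spec)
        fwd = forward_batch(params, make_batch([graph]))
        imp = fwd["node_imp"].data  # (n, K)
        bonds = [(b[0], b[1]) for b in rec.molecule.bonds]
        for k in range(params.config.num_channels):
            emb = fwd["node_emb"][k].data  # (n, d)
            selected = imp[:, k] >= threshold
            for comp in _connected_components(selected, bonds):
                if len(comp) < 2:
                    continue
                w = imp[comp, k]
                vec = (w[:, None] * emb[comp]).sum(axis=0) / w.sum()
                out.append(
                    SubgraphEmbedding(
                        source_id=rec.source_id,
                        source_smiles=rec.molecule.canonical_form,
                        channel=k,
                        atom_indices=tuple(comp),
                        vector=vec,
                    )
                )
    return out


def cluster_concepts(
    embeddings: list[SubgraphEmbedding],
    min_cluster_size: int = 5,
    seed: int = 0,
    n_components: int = 8,
) -> list[ConceptCluster]:
    """Channel-wise density clustering of subgraph embeddings.

    Channels are clustered independently (no cluster mixes channels); DBSCAN
    noise points belong to no cluster. The DBSCAN radius is set from the data
    as the median distance to the (min_cluster_size-1)-th nearest neighbour,
    which adapts to the embedding scale and stays deterministic.
    """
    if len(embeddings) < min_cluster_size:
        return []
    clusters: list[ConceptCluster] = []
    next_id = 0
    for channel in sorted({e.channel for e in embeddings}):
        members = [e for e in embeddings if e.channel == channel]
        if len(members) < min_cluster_size:
            continue
        X = np.stack([e.vector for e in members])
        if X.shape[1] > n_components and X.shape[0] > n_components:
            X = PCA(n_components=n_components, random_state=seed).fit_transform(X)
        kth = min(min_cluster_size - 1, len(members) - 1)
        dists = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(axis=2))
        knn = np.sort(dists, axis=1)[:, kth]
        eps = max(float(np.median(knn)), 1e-8)
        labels = DBSCAN(eps=eps, min_samples=min_cluster_size).fit_predict(X)
        for lab in sorted(set(labels) - {-1}):
            sel = np.flatnonzero(labels == lab)
            centroid = X[sel].mean(axis=0)
            order = sel[np.argsort(((X[sel] - centroid) ** 2).sum(axis=1), kind="stable")]
            reps = []
            for i in order:
                pair = (members[i].source_id, members[i].source_smiles)
                if pair not in reps:
                    reps.append(pair)
                if len(reps) == 10:
                    break
            clusters.append(
                ConceptCluster(
                    cluster_id=next_id,
                    channel=channel,
                    members=[members[i] for i in sel],
                    centroid=centroid,
                    representatives=reps,
                )
            )
            next_id += 1
    return clusters


def _consensus_substructure(cluster: ConceptCluster, timeout: int = 5) -> str:
    """MCS SMARTS of up to 10 representatives; falls back to the most frequent
    member fragment when the MCS is degenerate."""
    mols = []
    for _id, smi in cluster.representatives[:10]:
        m = Chem.MolFromSmiles(smi)
        if m is not None:
            mols.append(m)
    if len(mols) >= 2:
        mcs = rdFMCS.FindMCS(mols, timeout=timeout, matchValences=False,
                             ringMatchesRingOnly=False)
        if not mcs.canceled and mcs.numAtoms >= 2:
            return mcs.smartsString
    frags = []
    for member in cluster.members:
        m = Chem.MolFromSmiles(member.source_smiles)
        if m is None:
            continue
        try:
            frags.append(
                Chem.MolFragmentToSmiles(m, atomsToUse=list(member.atom_indices))
            )
        except Exception:
            continue
    if frags:
        return Counter(frags).most_common(1)[0][0]
    return ""


def concept_report(clusters: list[ConceptCluster]) -> dict:
    """Totals per channel plus per-cluster summaries (size, representatives,
    consensus substructure)."""
    report = {
        "totals": {
            "all": len(clusters),
            **{f"channel_{k}": sum(1 for c in clusters if c.channel == k) for k in (0, 1)},
        },
        "clusters": [],
    }
    for c in sorted(clusters, key=lambda c: c.cluster_id):
        report["clusters"].append(
            {
                "cluster_id": c.cluster_id,
                "channel": c.channel,
                "size": c.size,
                "representatives": [smi for _id, smi in c.representatives],
                "consensus_substructure": _consensus_substructure(c),
            }
        )
    return report
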