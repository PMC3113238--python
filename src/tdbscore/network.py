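"""Bipartite metabolite-reaction networks: data model, edge-list I/O, and
reconstruction preprocessing.

A genome-scale metabolic reconstruction is represented here in its simplest
topological form: an undirected, unweighted bipartite graph in which one node
class holds metabolites, the other holds reactions, and an edge (m, r) states
that metabolite m participates in reaction r. Stoichiometry, directionality
and the substrate/product distinction are deliberately discarded; the scoring
models downstream operate on this topology alone.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "BipartiteNetwork",
    "ReactionRecord",
    "DegreeSummary",
    "EdgeListError",
    "BipartivityError",
    "read_edge_list",
    "write_edge_list",
    "read_reaction_table",
    "write_reaction_table",
    "preprocess_records",
    "preprocess_reconstruction",
    "degree_summary",
]


class EdgeListError(ValueError):
    """Malformed edge-list input (carries the offending line number)."""


class BipartivityError(ValueError):
    """A label was used both as a metabolite and as a reaction."""


@dataclass(frozen=True)
class BipartiteNetwork:
    """An undirected bipartite metabolite-reaction graph.

    Node identity is by label. ``metabolite_ids`` and ``reaction_ids`` are
    kept sorted so that array representations (biadjacency, probability
    matrices) are deterministic. Nodes of degree zero are permitted only when
    the node lists are given explicitly (e.g. after link removal in
    robustness tests); networks built from an edge list have no dangling
    ends by construction.
    """

    metabolite_ids: tuple[str, ...]
    reaction_ids: tuple[str, ...]
    edges: frozenset[tuple[str, str]]

    def __post_init__(self) -> None:
        mset = set(self.metabolite_ids)
        rset = set(self.reaction_ids)
        if len(mset) != len(self.metabolite_ids) or len(rset) != len(self.reaction_ids):
            raise ValueError("duplicate node labels within a partition")
        overlap = mset & rset
        if overlap:
            raise BipartivityError(
                f"labels present in both partitions: {sorted(overlap)[:5]}"
            )
        for m, r in self.edges:
            if m not in mset or r not in rset:
                raise BipartivityError(f"edge ({m!r}, {r!r}) leaves the bipartition")

    # -- constructors ------------------------------------------------------

    @classmethod
    def from_edges(cls, edges: Iterable[tuple[str, str]]) -> "BipartiteNetwork":
        """Build a network whose node sets are inferred from the edges."""
        es = frozenset((str(m), str(r)) for m, r in edges)
        mets = tuple(sorted({m for m, _ in es}))
        rxns = tuple(sorted({r for _, r in es}))
        return cls(mets, rxns, es)

    # -- basic counts ------------------------------------------------------

    @property
    def M(self) -> int:
        return len(self.metabolite_ids)

    @property
    def R(self) -> int:
        return len(self.reaction_ids)

    @property
    def L(self) -> int:
        return len(self.edges)

    # -- degrees and indexing ---------------------------------------------

    def metabolite_degrees(self) -> dict[str, int]:
        k = dict.fromkeys(self.metabolite_ids, 0)
        for m, _ in self.edges:
            k[m] += 1
        return k

    def reaction_degrees(self) -> dict[str, int]:
        k = dict.fromkeys(self.reaction_ids, 0)
        for _, r in self.edges:
            k[r] += 1
        return k

    def metabolite_index(self) -> dict[str, int]:
        return {m: i for i, m in enumerate(self.metabolite_ids)}

    def reaction_index(self) -> dict[str, int]:
        return {r: j for j, r in enumerate(self.reaction_ids)}

    def biadjacency(self) -> np.ndarray:
        """Boolean M x R incidence matrix in sorted-label order."""
        B = np.zeros((self.M, self.R), dtype=bool)
        mi, ri = self.metabolite_index(), self.reaction_index()
        for m, r in self.edges:
            B[mi[m], ri[r]] = True
        return B

    def reaction_members(self) -> dict[str, frozenset[str]]:
        """Metabolite set of each reaction."""
        nu: dict[str, set[str]] = {r: set() for r in self.reaction_ids}
        for m, r in self.edges:
            nu[r].add(m)
        return {r: frozenset(s) for r, s in nu.items()}

    def remove_edges(self, removed: Iterable[tuple[str, str]]) -> "BipartiteNetwork":
        """Return a copy with the given edges removed but all nodes retained.

        Nodes isolated by the removal stay in the partition lists with degree
        zero (logged), so probability matrices keep their shape.
        """
        rem = frozenset(removed)
        missing = rem - self.edges
        if missing:
            raise ValueError(f"cannot remove absent edges: {sorted(missing)[:5]}")
        kept = self.edges - rem
        net = BipartiteNetwork(self.metabolite_ids, self.reaction_ids, kept)
        touched = {m for m, _ in kept} | {r for _, r in kept}
        isolated = (set(self.metabolite_ids) | set(self.reaction_ids)) - touched
        if isolated:
            logger.info("edge removal isolated %d node(s); retained with degree 0",
                        len(isolated))
        return net


@dataclass(frozen=True)
class ReactionRecord:
    """One reaction row of a reconstruction table.

    ``flags`` marks the classes that the preprocessing filters act on:
    'exchange', 'diffusion', 'isomerization'. ``confidence`` is the discrete
    database evidence score (4 = direct biochemical proof ... 0 = included
    for modelling reasons only), or None when unannotated.
    """

    reaction_id: str
    metabolites: frozenset[str]
    confidence: int | None = None
    subsystem: str | None = None
    flags: frozenset[str] = field(default_factory=frozenset)

    _KNOWN_FLAGS = frozenset({"exchange", "diffusion", "isomerization"})

    def __post_init__(self) -> None:
        if not self.metabolites:
            raise ValueError(f"reaction {self.reaction_id!r} has no metabolites")
        if self.confidence is not None and self.confidence not in range(5):
            raise ValueError(
                f"confidence score must be in 0..4, got {self.confidence!r}"
            )
        unknown = self.flags - self._KNOWN_FLAGS
        if unknown:
            raise ValueError(f"unknown flags {sorted(unknown)}")


@dataclass(frozen=True)
class DegreeSummary:
    """Per-partition degree statistics of a bipartite network."""

    mean_k_m: float
    mean_k_r: float
    mode_k_m: int
    mode_k_r: int
    max_k_m: int
    max_k_r: int
    hist_k_m: dict[int, int]
    hist_k_r: dict[int, int]


# ---------------------------------------------------------------------------
# Edge-list I/O
# ---------------------------------------------------------------------------

def read_edge_list(path: str | Path, metabolite_first: bool = True) -> BipartiteNetwork:
    """Read a two-column whitespace/tab-separated edge list.

    Lines starting with '#' and blank lines are skipped. Duplicate edges
    collapse (set semantics). ``metabolite_first=False`` flips the column
    order for files written reaction-first.
    """
    path = Path(path)
    edges: set[tuple[str, str]] = set()
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 2:
                raise EdgeListError(
                    f"{path}:{lineno}: expected 2 columns, got {len(parts)}"
                )
            a, b = parts
            edges.add((a, b) if metabolite_first else (b, a))
    mets = {m for m, _ in edges}
    rxns = {r for _, r in edges}
    overlap = mets & rxns
    if overlap:
        raise BipartivityError(
            f"{path}: labels appear in both columns: {sorted(overlap)[:5]}"
        )
    return BipartiteNetwork.from_edges(edges)


def write_edge_list(net: BipartiteNetwork, path: str | Path) -> None:
    """Write the network as a metabolite-first tab-separated edge list.

    Round-trips through :func:`read_edge_list`. Labels containing whitespace
    are rejected (the format cannot represent them); an edgeless network is
    rejected because the reader could not recover its node sets.
    """
    if net.L == 0:
        raise ValueError("refusing to write a network with no edges")
    for label in (*net.metabolite_ids, *net.reaction_ids):
        if label != label.strip() or any(c.isspace() for c in label):
            raise ValueError(f"label {label!r} contains whitespace")
    path = Path(path)
    with path.open("w") as fh:
        fh.write("# metabolite\treaction\n")
        for m, r in sorted(net.edges):
            fh.write(f"{m}\t{r}\n")


# ---------------------------------------------------------------------------
# Reaction-table I/O
# ---------------------------------------------------------------------------
# Format: tab-separated with a '#'-header; columns are
#   reaction_id, semicolon-joined metabolites, confidence ('' if absent),
#   subsystem ('' if absent), comma-joined flags ('' if none).

def read_reaction_table(path: str | Path) -> list[ReactionRecord]:
    path = Path(path)
    records: list[ReactionRecord] = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 5:
                raise EdgeListError(
                    f"{path}:{lineno}: expected 5 tab-separated columns, got {len(parts)}"
                )
            rid, mets, conf, subsystem, flags = parts
            records.append(
                ReactionRecord(
                    reaction_id=rid,
                    metabolites=frozenset(m for m in mets.split(";") if m),
                    confidence=int(conf) if conf else None,
                    subsystem=subsystem or None,
                    flags=frozenset(f for f in flags.split(",") if f),
                )
            )
    return records


def write_reaction_table(records: Sequence[ReactionRecord], path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("# reaction_id\tmetabolites\tconfidence\tsubsystem\tflags\n")
        for rec in records:
            fh.write(
                "\t".join(
                    [
                        rec.reaction_id,
                        ";".join(sorted(rec.metabolites)),
                        "" if rec.confidence is None else str(rec.confidence),
                        rec.subsystem or "",
                        ",".join(sorted(rec.flags)),
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Reconstruction preprocessing
# ---------------------------------------------------------------------------

def _resolve(label: str, isomer_map: Mapping[str, str]) -> str:
    seen = {label}
    while label in isomer_map:
        label = isomer_map[label]
        if label in seen:
            raise ValueError(f"isomer merge cycle at {label!r}")
        seen.add(label)
    return label


def preprocess_records(
    records: Sequence[ReactionRecord],
    isomer_map: Mapping[str, str] | None = None,
    drop_metabolites: Iterable[str] = (),
) -> list[ReactionRecord]:
    """Apply the curation filters that make a reconstruction a clean bigraph.

    In order: drop exchange- and diffusion-flagged reactions (they create
    dangling ends or self-connections in the undirected picture); drop
    isomerization reactions and merge each isomer pair onto a single
    metabolite label, but only for pairs listed in ``isomer_map`` (i.e. only
    when an isomerizing reaction identified the pair); remove the metabolites
    listed in ``drop_metabolites``; finally drop reactions left with no
    metabolites. The result has no degree-0 nodes and the function is
    idempotent.
    """
    isomer_map = dict(isomer_map or {})
    drop = set(drop_metabolites)
    out: list[ReactionRecord] = []
    for rec in records:
        if rec.flags & {"exchange", "diffusion", "isomerization"}:
            continue
        merged = {_resolve(m, isomer_map) for m in rec.metabolites}
        if len(merged) < len(rec.metabolites):
            logger.warning(
                "reaction %s: isomer merge collapsed %d metabolite(s)",
                rec.reaction_id, len(rec.metabolites) - len(merged),
            )
        merged -= drop
        if not merged:
            logger.info("reaction %s dropped: no metabolites left", rec.reaction_id)
            continue
        out.append(
            ReactionRecord(
                reaction_id=rec.reaction_id,
                metabolites=frozenset(merged),
                confidence=rec.confidence,
                subsystem=rec.subsystem,
                flags=frozenset(),
            )
        )
    return out


def preprocess_reconstruction(
    records: Sequence[ReactionRecord],
    isomer_map: Mapping[str, str] | None = None,
    drop_metabolites: Iterable[str] = (),
) -> BipartiteNetwork:
    """Filter a reconstruction table and return the resulting bipartite network."""
    kept = preprocess_records(records, isomer_map, drop_metabolites)
    edges = [(m, rec.reaction_id) for rec in kept for m in rec.metabolites]
    return BipartiteNetwork.from_edges(edges)


# ---------------------------------------------------------------------------
# Degree summary
# ---------------------------------------------------------------------------

def degree_summary(net: BipartiteNetwork) -> DegreeSummary:
    """Mean/mode/max degree per partition plus degree histograms.

    Satisfies mean_k_r * R == mean_k_m * M == L. Mode ties break to the
    smallest degree.
    """
    km = list(net.metabolite_degrees().values())
    kr = list(net.reaction_degrees().values())
    hm, hr = Counter(km), Counter(kr)

    def _mode(h: Counter) -> int:
        best = max(h.values())
        return min(k for k, c in h.items() if c == best)

    return DegreeSummary(
        mean_k_m=float(np.mean(km)),
        mean_k_r=float(np.mean(kr)),
        mode_k_m=_mode(hm),
        mode_k_r=_mode(hr),
        max_k_m=max(km),
        max_k_r=max(kr),
        hist_k_m=dict(sorted(hm.items())),
        hist_k_r=dict(sorted(hr.items())),
    )
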