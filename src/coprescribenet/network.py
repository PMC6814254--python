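"""Patient co-prescription network construction.

A bipartite patient–prescriber graph is built from opioid prescription
claims (medication-assisted-treatment agents excluded), pooled over a
trailing three-quarter window around a focal quarter.  Its one-mode
projection is an undirected patient–patient graph in which two patients
are tied iff they received opioids from at least one common prescriber;
the tie weight is the number of unique shared prescribers.  Isolate
patients are retained as nodes so that prominence metrics are defined
for the whole analysis panel.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx
import pandas as pd

__all__ = [
    "BipartiteGraph",
    "CoPrescriptionGraph",
    "filter_opioid_claims",
    "pooled_window",
    "build_bipartite",
    "project_patients",
]


def filter_opioid_claims(rx: pd.DataFrame) -> pd.DataFrame:
    """Drop medication-assisted-treatment (MAT) fills, e.g. buprenorphine.

    MAT prescribers are sparsely located and induce spurious clustering,
    so MAT agents never enter the network.  Row order is preserved.
    """
    if "is_mat" not in rx.columns:
        raise ValueError("prescription table lacks an 'is_mat' column")
    return rx.loc[rx["is_mat"] == 0].copy()


def pooled_window(
    focal_quarter: int,
    width: int = 3,
    min_quarter: int = 0,
    max_quarter: int | None = None,
    policy: str = "truncate",
) -> list[int]:
    """Quarters pooled into the network for a focal quarter: {T-2, T-1, T}.

    Pooling smooths the arbitrary cut points of quarterly observation and
    allows for lags in information diffusion.  Early quarters with fewer
    than ``width - 1`` predecessors pool what exists (``policy='truncate'``)
    or raise (``policy='drop'``).
    """
    if max_quarter is not None and (focal_quarter < min_quarter or focal_quarter > max_quarter):
        raise ValueError(
            f"focal quarter {focal_quarter} outside data range "
            f"[{min_quarter}, {max_quarter}]"
        )
    if focal_quarter < min_quarter:
        raise ValueError(f"focal quarter {focal_quarter} before first quarter {min_quarter}")
    lo = focal_quarter - width + 1
    if lo < min_quarter:
        if policy == "drop":
            raise ValueError(
                f"focal quarter {focal_quarter} has an incomplete {width}-quarter window"
            )
        lo = min_quarter
    return list(range(lo, focal_quarter + 1))


@dataclass
class BipartiteGraph:
    """Two-mode patient–prescriber graph for one pooled window.

    An edge (patient, prescriber) is present iff the prescriber wrote at
    least one non-MAT opioid fill for that patient within the window;
    multiplicity is not retained.  All panel patients appear as nodes
    even when isolated.
    """

    patients: list
    prescribers: list
    patient_adj: dict = field(repr=False)   # patient -> set of prescribers
    prescriber_adj: dict = field(repr=False)  # prescriber -> set of patients
    focal_quarter: int | None = None
    window: list[int] | None = None

    @property
    def n_edges(self) -> int:
        return sum(len(s) for s in self.patient_adj.values())

    def edges(self) -> set[tuple]:
        return {(p, d) for p, ds in self.patient_adj.items() for d in ds}


def build_bipartite(
    rx_filtered: pd.DataFrame,
    focal_quarter: int,
    width: int = 3,
    patients=None,
    min_quarter: int = 0,
    max_quarter: int | None = None,
    window_policy: str = "truncate",
) -> BipartiteGraph:
    """Build the patient–prescriber graph for one focal quarter.

    Parameters
    ----------
    rx_filtered : prescription table already passed through
        :func:`filter_opioid_claims`.
    patients : optional explicit node list; defaults to the patients
        appearing anywhere in ``rx_filtered`` (any quarter), so isolates
        in the focal window are retained.
    """
    window = pooled_window(
        focal_quarter, width=width, min_quarter=min_quarter,
        max_quarter=max_quarter, policy=window_policy,
    )
    in_win = rx_filtered.loc[rx_filtered["quarter"].isin(window)]
    pairs = in_win[["patient_id", "prescriber_id"]].drop_duplicates()

    if patients is None:
        patients = sorted(rx_filtered["patient_id"].unique())
    else:
        patients = sorted(patients)

    patient_adj: dict = {p: set() for p in patients}
    prescriber_adj: dict = {}
    for p, d in zip(pairs["patient_id"].to_numpy(), pairs["prescriber_id"].to_numpy()):
        if p not in patient_adj:      # patient outside the panel: skip
            continue
        patient_adj[p].add(d)
        prescriber_adj.setdefault(d, set()).add(p)

    return BipartiteGraph(
        patients=list(patients),
        prescribers=sorted(prescriber_adj),
        patient_adj=patient_adj,
        prescriber_adj=prescriber_adj,
        focal_quarter=focal_quarter,
        window=window,
    )


@dataclass
class CoPrescriptionGraph:
    """Undirected weighted patient–patient graph for one focal quarter.

    ``graph`` is a :class:`networkx.Graph` whose nodes are all panel
    patients (isolates included) and whose edge attribute ``weight`` is
    the number of unique shared prescribers, w_ij = |N(i) ∩ N(j)|.
    """

    graph: nx.Graph
    focal_quarter: int | None = None
    window: list[int] | None = None

    def strength(self) -> dict:
        """s_i = Σ_j w_ij, the weighted degree; 0 for isolates."""
        return {n: float(d) for n, d in self.graph.degree(weight="weight")}

    def total_weight(self) -> float:
        return sum(d["weight"] for _, _, d in self.graph.edges(data=True))


def project_patients(bip: BipartiteGraph) -> CoPrescriptionGraph:
    """One-mode projection of the bipartite graph onto patients.

    Enumerates patient pairs per prescriber (sparse combination counting),
    so the cost is Σ_d C(deg(d), 2) rather than |patients|².  The result
    is independent of enumeration order.  Conservation law (tested):
    Σ_{a<b} w_ab == Σ_d C(deg(d), 2).
    """
    counts: dict[tuple, int] = {}
    for pts in bip.prescriber_adj.values():
        for a, b in combinations(sorted(pts), 2):
            key = (a, b)
            counts[key] = counts.get(key, 0) + 1

    g = nx.Graph()
    g.add_nodes_from(bip.patients)
    g.add_weighted_edges_from((a, b, w) for (a, b), w in counts.items())
    return CoPrescriptionGraph(graph=g, focal_quarter=bip.focal_quarter, window=bip.window)


def write_edge_list(cg: CoPrescriptionGraph, path) -> None:
    """Write the projected graph as a delimited edge list (isolates implicit)."""
    rows = [
        {"patient_a": a, "patient_b": b, "weight": d["weight"],
         "focal_quarter": cg.focal_quarter}
        for a, b, d in cg.graph.edges(data=True)
    ]
    pd.DataFrame(rows, columns=["patient_a", "patient_b", "weight", "focal_quarter"]).to_csv(
        path, index=False
    )


def read_edge_list(path, patients=None) -> CoPrescriptionGraph:
    df = pd.read_csv(path)
    g = nx.Graph()
    if patients is not None:
        g.add_nodes_from(patients)
    g.add_weighted_edges_from(
        zip(df["patient_a"], df["patient_b"], df["weight"].astype(float))
    )
    fq = int(df["focal_quarter"].iloc[0]) if len(df) else None
    return CoPrescriptionGraph(graph=g, focal_quarter=fq)
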