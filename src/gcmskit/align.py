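"""Dynamic-programming peak alignment across experiments, and common-ion
single-ion quantitation.

Peaks from two rt-sorted lists are aligned with a Needleman-Wunsch-style
global DP that minimizes total cost: matching two peaks costs
``1 - similarity`` and leaving a peak unmatched costs the flat gap penalty
``G``. Peak-to-peak similarity is the cosine of the two composite spectra
modulated by a Gaussian in the retention-time difference,

    sim(p, q) = cos(s_p, s_q) * exp(-(rt_p - rt_q)^2 / (2 D^2)),

so identical spectra at equal rt score 1 and orthogonal spectra score 0
regardless of rt. Multiple experiments are aligned progressively along a
guide tree built by average-linkage agglomeration of the pairwise alignment
costs; a profile position scores against another as the mean similarity
over its defined members.

Common-ion quantitation then inspects each aligned position: the top-N ion
sets of the member peaks are intersected and, when the intersection is
non-empty, the single shared ion is used for quantitation in every
experiment (its per-ion area as integrated over each member's own bounds).
An empty intersection flags the position as probably misaligned.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .peaks import Peak

__all__ = [
    "AlignmentParams",
    "AlignmentTable",
    "QuantitationResult",
    "peak_similarity",
    "align_pair",
    "build_guide_tree",
    "align_all",
    "area_matrix",
    "common_ion_quantify",
    "write_alignment_csv",
    "read_alignment_csv",
]

DEFAULT_D = 2.5
DEFAULT_GAP = 0.30
DEFAULT_COMMON_ION_N = 5


@dataclass(frozen=True)
class AlignmentParams:
    """D: rt-modulation width (s); gap: gap penalty in [0,1]; min_peaks:
    minimum occupancy for a position to be kept in the final table."""

    D: float = DEFAULT_D
    gap: float = DEFAULT_GAP
    min_peaks: int = 1

    def __post_init__(self) -> None:
        if self.D <= 0:
            raise ValueError("D must be positive")
        if not 0 <= self.gap <= 1:
            raise ValueError("gap penalty must lie in [0, 1]")
        if self.min_peaks < 1:
            raise ValueError("min_peaks must be >= 1")


@dataclass(frozen=True)
class AlignmentTable:
    """Aligned peak positions: one optional Peak per experiment per row.

    Rows are ordered by consensus rt; within each experiment column the rts
    of assigned peaks are non-decreasing (elution order is preserved), and
    every input peak appears in exactly one row.
    """

    experiment_ids: tuple[str, ...]
    rows: tuple[tuple[Peak | None, ...], ...]

    def __post_init__(self) -> None:
        for row in self.rows:
            if len(row) != len(self.experiment_ids):
                raise ValueError("row width must equal the number of experiments")

    @property
    def n_positions(self) -> int:
        return len(self.rows)

    def consensus_rt(self, row_index: int) -> float:
        rts = [p.rt for p in self.rows[row_index] if p is not None]
        return float(np.mean(rts))

    def occupancy(self, row_index: int) -> int:
        return sum(1 for p in self.rows[row_index] if p is not None)

    def row_uid(self, row_index: int) -> str:
        """UID of the most intense member (ties to the first experiment)."""
        members = [p for p in self.rows[row_index] if p is not None]
        best = max(members, key=lambda p: max(p.member_ions().values()))
        return best.uid


@dataclass(frozen=True)
class QuantitationResult:
    """Per-position common quantitation ion, per-cell single-ion areas, and
    misalignment flags (flagged positions carry no areas)."""

    common_ions: tuple[float | None, ...]
    areas: tuple[tuple[float | None, ...], ...]
    misaligned: tuple[bool, ...]


def _spectrum_vectors(p: Peak, q: Peak) -> tuple[np.ndarray, np.ndarray]:
    a, b = p.member_ions(), q.member_ions()
    masses = sorted(set(a) | set(b))
    va = np.array([a.get(m, 0.0) for m in masses])
    vb = np.array([b.get(m, 0.0) for m in masses])
    return va, vb


def peak_similarity(p: Peak, q: Peak, D: float = DEFAULT_D) -> float:
    """Cosine spectral similarity modulated by a Gaussian rt term; in [0, 1]."""
    va, vb = _spectrum_vectors(p, q)
    na, nb = np.linalg.norm(va), np.linalg.norm(vb)
    if na == 0 or nb == 0:
        raise ValueError("peak similarity undefined for a zero spectrum")
    cosine = float(np.dot(va, vb) / (na * nb))
    rt_term = math.exp(-((p.rt - q.rt) ** 2) / (2.0 * D * D))
    return cosine * rt_term


def _check_sorted(peaks: Sequence[Peak], name: str) -> None:
    rts = [p.rt for p in peaks]
    if any(b < a for a, b in zip(rts, rts[1:])):
        raise ValueError(f"peak list {name!r} must be sorted by retention time")


_Row = tuple  # row of Peak | None, one slot per experiment in the table


def _merge_tables(
    ta: AlignmentTable, tb: AlignmentTable, params: AlignmentParams
) -> AlignmentTable:
    """Global DP alignment of two alignment tables (profile alignment).

    Cost: matching two positions costs 1 - mean pairwise member similarity;
    a gap costs ``params.gap`` regardless of profile width. Traceback ties
    prefer a match; between the two gap moves the position eluting earlier
    is consumed first (symmetric in the inputs).
    """
    na, nb = ta.n_positions, tb.n_positions
    gap = params.gap
    sim = np.zeros((na, nb))
    for i in range(na):
        pa = [p for p in ta.rows[i] if p is not None]
        for j in range(nb):
            pb = [q for q in tb.rows[j] if q is not None]
            sims = [peak_similarity(p, q, params.D) for p in pa for q in pb]
            sim[i, j] = float(np.mean(sims))
    cost = np.empty((na + 1, nb + 1))
    cost[:, 0] = np.arange(na + 1) * gap
    cost[0, :] = np.arange(nb + 1) * gap
    for i in range(1, na + 1):
        for j in range(1, nb + 1):
            cost[i, j] = min(
                cost[i - 1, j - 1] + 1.0 - sim[i - 1, j - 1],
                cost[i - 1, j] + gap,
                cost[i, j - 1] + gap,
            )
    # traceback
    width_a, width_b = len(ta.experiment_ids), len(tb.experiment_ids)
    gap_a: _Row = (None,) * width_a
    gap_b: _Row = (None,) * width_b
    merged: list[tuple[_Row, _Row]] = []
    i, j = na, nb
    eps = 1e-12
    while i > 0 or j > 0:
        if (
            i > 0
            and j > 0
            and abs(cost[i, j] - (cost[i - 1, j - 1] + 1.0 - sim[i - 1, j - 1])) < eps
        ):
            merged.append((ta.rows[i - 1], tb.rows[j - 1]))
            i, j = i - 1, j - 1
            continue
        up_ok = i > 0 and abs(cost[i, j] - (cost[i - 1, j] + gap)) < eps
        left_ok = j > 0 and abs(cost[i, j] - (cost[i, j - 1] + gap)) < eps
        if up_ok and left_ok:
            # consume the later-eluting position first (we build back-to-front)
            if ta.consensus_rt(i - 1) >= tb.consensus_rt(j - 1):
                left_ok = False
            else:
                up_ok = False
        if up_ok:
            merged.append((ta.rows[i - 1], gap_b))
            i -= 1
        else:
            merged.append((gap_a, tb.rows[j - 1]))
            j -= 1
    merged.reverse()
    rows = tuple(ra + rb for ra, rb in merged)
    return AlignmentTable(ta.experiment_ids + tb.experiment_ids, rows)


def _as_table(peaks: Sequence[Peak], experiment_id: str) -> AlignmentTable:
    _check_sorted(peaks, experiment_id)
    return AlignmentTable((experiment_id,), tuple((p,) for p in peaks))


def _alignment_cost(
    a: Sequence[Peak], b: Sequence[Peak], params: AlignmentParams
) -> float:
    """Optimal DP cost of aligning two peak lists (used for the guide tree)."""
    na, nb = len(a), len(b)
    sim = np.array([[peak_similarity(p, q, params.D) for q in b] for p in a])
    cost = np.empty((na + 1, nb + 1))
    cost[:, 0] = np.arange(na + 1) * params.gap
    cost[0, :] = np.arange(nb + 1) * params.gap
    for i in range(1, na + 1):
        for j in range(1, nb + 1):
            cost[i, j] = min(
                cost[i - 1, j - 1] + 1.0 - sim[i - 1, j - 1],
                cost[i - 1, j] + params.gap,
                cost[i, j - 1] + params.gap,
            )
    return float(cost[na, nb])


def align_pair(
    a: Sequence[Peak],
    b: Sequence[Peak],
    params: AlignmentParams | None = None,
    experiment_ids: tuple[str, str] = ("exp0", "exp1"),
) -> AlignmentTable:
    """Globally align two rt-sorted peak lists by dynamic programming."""
    params = params or AlignmentParams()
    ta = _as_table(a, experiment_ids[0])
    tb = _as_table(b, experiment_ids[1])
    if not a:
        return AlignmentTable(
            experiment_ids, tuple((None, q) for q in b)
        )
    if not b:
        return AlignmentTable(
            experiment_ids, tuple((p, None) for p in a)
        )
    return _merge_tables(ta, tb, params)


def build_guide_tree(
    experiments: Sequence[Sequence[Peak]], params: AlignmentParams | None = None
) -> list[tuple[int, int]]:
    """Merge order for progressive alignment.

    All pairwise alignment costs are computed; average-linkage agglomeration
    yields the merge sequence as ``(cluster_i, cluster_j)`` pairs using the
    scipy convention (leaves 0..n-1, the k-th merge creates cluster n+k).
    Ties resolve by input order. Two experiments yield the single merge
    ``[(0, 1)]``.
    """
    params = params or AlignmentParams()
    n = len(experiments)
    if n < 2:
        raise ValueError("need at least two experiments")
    if n == 2:
        return [(0, 1)]
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dist[i, j] = dist[j, i] = _alignment_cost(
                experiments[i], experiments[j], params
            )
    z = linkage(squareform(dist, checks=False), method="average")
    return [(int(row[0]), int(row[1])) for row in z]


def align_all(
    experiments: Sequence[Sequence[Peak]],
    params: AlignmentParams | None = None,
    experiment_ids: Sequence[str] | None = None,
) -> AlignmentTable:
    """Progressive multi-experiment alignment along the guide tree.

    The final table's experiment columns are restored to input order, and
    positions occupied by fewer than ``params.min_peaks`` members are
    dropped.
    """
    params = params or AlignmentParams()
    n = len(experiments)
    ids = tuple(experiment_ids) if experiment_ids else tuple(f"exp{i}" for i in range(n))
    if len(ids) != n:
        raise ValueError("experiment_ids length mismatch")
    clusters: dict[int, AlignmentTable] = {
        i: _as_table(exp, ids[i]) for i, exp in enumerate(experiments)
    }
    next_id = n
    for ci, cj in build_guide_tree(experiments, params):
        clusters[next_id] = _merge_tables(clusters.pop(ci), clusters.pop(cj), params)
        next_id += 1
    table = clusters[next_id - 1]
    order = [table.experiment_ids.index(e) for e in ids]
    rows = tuple(
        tuple(row[k] for k in order)
        for row in table.rows
        if sum(1 for p in row if p is not None) >= params.min_peaks
    )
    return AlignmentTable(ids, rows)


def area_matrix(table: AlignmentTable) -> pd.DataFrame:
    """Positions x experiments grid of total peak areas (NaN marks a gap).

    The index carries each position's UID; a ``rt_s`` column holds the
    consensus retention time.
    """
    records = []
    for k in range(table.n_positions):
        rec: dict[str, float | None] = {"rt_s": table.consensus_rt(k)}
        for exp, peak in zip(table.experiment_ids, table.rows[k]):
            rec[exp] = peak.area if peak is not None else np.nan
        records.append(rec)
    index = [table.row_uid(k) for k in range(table.n_positions)]
    return pd.DataFrame(records, index=pd.Index(index, name="uid"))


def common_ion_quantify(
    table: AlignmentTable, n_top: int = DEFAULT_COMMON_ION_N
) -> QuantitationResult:
    """Select one quantitation ion per position and read its per-ion areas.

    The top-``n_top`` ion sets of all member peaks are intersected.
    Candidates are ranked by their summed intensity rank across members
    (most intense overall first, ties to the lower m/z); the winner's
    per-ion area — already integrated over each member's own bounds during
    peak quantitation — becomes the cell value. Positions with an empty
    intersection are flagged misaligned and receive no areas.
    """
    common_ions: list[float | None] = []
    all_areas: list[tuple[float | None, ...]] = []
    misaligned: list[bool] = []
    for row in table.rows:
        members = [p for p in row if p is not None]
        if not members:
            common_ions.append(None)
            all_areas.append(tuple(None for _ in row))
            misaligned.append(False)
            continue
        top_sets = [p.top_ions(n_top) for p in members]
        shared = set(top_sets[0]).intersection(*map(set, top_sets[1:]))
        if not shared:
            common_ions.append(None)
            all_areas.append(tuple(None for _ in row))
            misaligned.append(True)
            continue
        rank_sum = {
            ion: sum(ranks.index(ion) for ranks in top_sets) for ion in shared
        }
        ion = min(shared, key=lambda m: (rank_sum[m], m))
        areas = tuple(
            (p.ion_areas.get(ion) if p is not None else None) for p in row
        )
        common_ions.append(ion)
        all_areas.append(areas)
        misaligned.append(False)
    return QuantitationResult(tuple(common_ions), tuple(all_areas), tuple(misaligned))


def write_alignment_csv(
    table: AlignmentTable,
    result: QuantitationResult | None,
    prefix: str | Path,
) -> tuple[Path, Path]:
    """Write the area matrix and companion metadata as two CSV files.

    ``<prefix>_areas.csv`` holds uid, consensus rt and one total-area column
    per experiment (gaps serialized as ``NA``); ``<prefix>_meta.csv`` holds
    the common quantitation ion, occupancy and misalignment flag per
    position.
    """
    prefix = Path(prefix)
    areas_path = prefix.parent / f"{prefix.name}_areas.csv"
    meta_path = prefix.parent / f"{prefix.name}_meta.csv"
    df = area_matrix(table)
    df.to_csv(areas_path, na_rep="NA")
    with meta_path.open("w", newline="") as fh:
        fh.write("uid,rt_s,occupancy,common_ion,misaligned\n")
        for k in range(table.n_positions):
            ion = result.common_ions[k] if result is not None else None
            flag = result.misaligned[k] if result is not None else False
            fh.write(
                f"{table.row_uid(k)},{table.consensus_rt(k)!r},"
                f"{table.occupancy(k)},"
                f"{'' if ion is None else format(ion, 'g')},{flag}\n"
            )
    return areas_path, meta_path


def read_alignment_csv(areas_path: str | Path) -> pd.DataFrame:
    """Round-trip partner of the area-matrix CSV."""
    return pd.read_csv(areas_path, index_col="uid", na_values=["NA"])
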