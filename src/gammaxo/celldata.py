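"""Packing of a dataset into per-cell arrays for the compiled kernel."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import CrossoverDataset, GroupScheme
from ._kernels import cell_loglik_kernel

#: Combinatorial guard: the sprinkling likelihood sums over 2^n pathway
#: assignments; more crossovers than this on one chromatid is a data error.
MAX_CROSSOVERS_PER_RECORD = 20

#: Grid resolution of the interpolation tables (points per table).
TABLE_POINTS = 1024


@dataclass
class _CellArrays:
    pos_flat: np.ndarray  # Morgans, non-empty records concatenated
    offsets: np.ndarray  # int64, len = n_nonempty + 1
    rec_Lidx: np.ndarray  # int64, index into L_unique per non-empty record
    L_unique: np.ndarray  # Morgans
    counts_empty: np.ndarray  # int64 aligned with L_unique
    n_records: int


class CellwiseData:
    """A dataset regrouped by (meiosis-group, chromosome-group) cell,
    with positions converted to Morgans, ready for the fast kernel."""

    def __init__(self, arrays: dict[tuple[int, int], _CellArrays]):
        self._arrays = arrays

    @property
    def cells(self) -> list[tuple[int, int]]:
        return sorted(self._arrays)

    @classmethod
    def from_dataset(cls, data: CrossoverDataset, scheme: GroupScheme) -> "CellwiseData":
        grouped: dict[tuple[int, int], dict] = {}
        for rec in data.records:
            cell = scheme.cell_of(rec)
            g = grouped.setdefault(cell, {"pos": [], "L_ne": [], "L_e": []})
            L = rec.length_cM / 100.0
            if rec.n_crossovers == 0:
                g["L_e"].append(L)
            else:
                if rec.n_crossovers > MAX_CROSSOVERS_PER_RECORD:
                    raise ValueError(
                        f"record {rec.meiosis_id}/{rec.chromosome} has "
                        f"{rec.n_crossovers} crossovers; subset-sum guard is "
                        f"{MAX_CROSSOVERS_PER_RECORD}"
                    )
                g["pos"].append(rec.positions / 100.0)
                g["L_ne"].append(L)
        arrays = {}
        for cell, g in grouped.items():
            all_L = np.asarray(g["L_ne"] + g["L_e"])
            L_unique = np.unique(all_L)
            lookup = {v: i for i, v in enumerate(L_unique)}
            counts_empty = np.zeros(L_unique.size, dtype=np.int64)
            for L in g["L_e"]:
                counts_empty[lookup[L]] += 1
            offsets = np.zeros(len(g["pos"]) + 1, dtype=np.int64)
            for i, pos in enumerate(g["pos"]):
                offsets[i + 1] = offsets[i] + pos.size
            pos_flat = (
                np.concatenate(g["pos"]) if g["pos"] else np.empty(0, dtype=float)
            )
            rec_Lidx = np.asarray([lookup[L] for L in g["L_ne"]], dtype=np.int64)
            arrays[cell] = _CellArrays(
                pos_flat, offsets, rec_Lidx, L_unique, counts_empty,
                n_records=len(g["L_ne"]) + len(g["L_e"]),
            )
        return cls(arrays)

    def cell_loglik(self, cell: tuple[int, int], nu: float, p: float) -> float:
        a = self._arrays[cell]
        return float(
            cell_loglik_kernel(
                float(nu), float(p), a.pos_flat, a.offsets, a.rec_Lidx,
                a.L_unique, a.counts_empty, TABLE_POINTS,
            )
        )
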