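"""Crossover data containers, readers, and descriptive statistics.

The atomic observation is a crossover on a transmitted chromatid, located in
centimorgans (cM) on the sex-specific genetic map. The likelihood unit is
the *transmitted chromosome*: one (meiosis, chromosome) cell with its map
length and the ordered (possibly empty) list of crossover positions.
A :class:`CrossoverDataset` covers every meiosis x chromosome cell, so
non-recombinant chromatids enter the likelihood with their full weight.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DataValidationError

SEXES = ("F", "M")
AUTOSOMES = tuple(str(c) for c in range(1, 20))

#: Two crossovers on one chromatid closer than this (cM) are treated as a
#: data error: below any real map resolution, and zero inter-arrival
#: distances have no density under the renewal model.
MIN_SEPARATION_CM = 1e-4

# Chromosome size bins used for the size-group analysis: each bin covers
# roughly one third of the cumulative genetic map.
SIZE_BINS = {
    "long": tuple(str(c) for c in range(1, 6)),
    "medium": tuple(str(c) for c in range(6, 13)),
    "short": tuple(str(c) for c in range(13, 20)),
}


class GeneticMapTable:
    """Sex-specific genetic length (cM) per chromosome.

    Defines the observation interval [0, L] for every transmitted
    chromosome.
    """

    def __init__(self, entries: Mapping[tuple[str, str], float]):
        self._entries: dict[tuple[str, str], float] = {}
        for (chrom, sex), length in entries.items():
            chrom, sex = str(chrom), str(sex)
            if sex not in SEXES:
                raise DataValidationError(f"unknown sex code {sex!r} in map table")
            if not np.isfinite(length) or length <= 0:
                raise DataValidationError(
                    f"non-positive map length for chromosome {chrom}, sex {sex}"
                )
            self._entries[(chrom, sex)] = float(length)

    def length(self, chromosome: str, sex: str) -> float:
        key = (str(chromosome), str(sex))
        if key not in self._entries:
            raise DataValidationError(
                f"no map entry for chromosome {key[0]}, sex {key[1]}"
            )
        return self._entries[key]

    @property
    def chromosomes(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for chrom, _ in self._entries:
            seen.setdefault(chrom, None)
        return tuple(seen)

    def total_length(self, sex: str) -> float:
        return sum(v for (c, s), v in self._entries.items() if s == sex)

    def validate_autosome_coverage(self, chromosomes: Iterable[str]) -> None:
        for chrom in chromosomes:
            for sex in SEXES:
                self.length(chrom, sex)

    @classmethod
    def from_tsv(cls, path) -> "GeneticMapTable":
        df = pd.read_csv(path, sep="\t", dtype={"chromosome": str})
        required = {"chromosome", "sex", "length_cM"}
        if not required.issubset(df.columns):
            raise DataValidationError(
                f"map table must have columns {sorted(required)}; got {list(df.columns)}"
            )
        return cls(
            {
                (row.chromosome, row.sex): row.length_cM
                for row in df.itertuples(index=False)
            }
        )

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"chromosome": c, "sex": s, "length_cM": v}
            for (c, s), v in sorted(
                self._entries.items(), key=lambda kv: (_chrom_order(kv[0][0]), kv[0][1])
            )
        ]
        return pd.DataFrame(rows)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def __eq__(self, other) -> bool:
        return isinstance(other, GeneticMapTable) and self._entries == other._entries


def _chrom_order(chrom: str) -> tuple[int, str]:
    try:
        return (int(chrom), "")
    except ValueError:
        return (1000, chrom)


def default_mouse_map() -> GeneticMapTable:
    """The bundled mouse map: 19 autosomes, 1,355 cM (female) / 1,221 cM
    (male) in total, declining monotonically from chromosome 1 to 19."""
    from importlib.resources import files

    return GeneticMapTable.from_tsv(files("gammaxo") / "mouse_map.tsv")


@dataclass(frozen=True)
class CrossoverEvent:
    """One crossover on a transmitted chromatid — the atomic observation."""

    meiosis_id: str
    sex: str
    chromosome: str
    position_cM: float


@dataclass(frozen=True)
class TransmittedChromosome:
    """One transmitted chromatid: the per-record likelihood unit."""

    meiosis_id: str
    sex: str
    chromosome: str
    length_cM: float
    positions: np.ndarray  # sorted crossover positions, cM

    def __post_init__(self):
        pos = np.asarray(self.positions, dtype=float)
        object.__setattr__(self, "positions", pos)
        if self.sex not in SEXES:
            raise DataValidationError(
                f"unknown sex code {self.sex!r} for meiosis {self.meiosis_id}"
            )
        if self.length_cM <= 0:
            raise DataValidationError(
                f"non-positive length for meiosis {self.meiosis_id}, "
                f"chromosome {self.chromosome}"
            )
        if pos.size:
            if np.any(pos < 0) or np.any(pos > self.length_cM):
                raise DataValidationError(
                    f"crossover position outside [0, {self.length_cM}] cM for "
                    f"meiosis {self.meiosis_id}, chromosome {self.chromosome}"
                )
            if np.any(np.diff(pos) < MIN_SEPARATION_CM):
                raise DataValidationError(
                    f"crossovers closer than {MIN_SEPARATION_CM} cM (or unsorted) "
                    f"for meiosis {self.meiosis_id}, chromosome {self.chromosome}"
                )

    @property
    def n_crossovers(self) -> int:
        return int(self.positions.size)


class CrossoverDataset:
    """All transmitted chromosomes of a cross, plus the genetic map.

    Covers every meiosis x chromosome cell exactly once; cells with no
    crossovers are explicit zero-crossover records.
    """

    def __init__(self, records: Sequence[TransmittedChromosome], map_table: GeneticMapTable):
        self.records = list(records)
        self.map = map_table
        seen: set[tuple[str, str]] = set()
        for rec in self.records:
            key = (rec.meiosis_id, rec.chromosome)
            if key in seen:
                raise DataValidationError(
                    f"duplicate record for meiosis {key[0]}, chromosome {key[1]}"
                )
            seen.add(key)
        meioses = self.meioses
        chroms = self.chromosomes
        if self.records and len(self.records) != len(meioses) * len(chroms):
            raise DataValidationError(
                f"record count {len(self.records)} != "
                f"{len(meioses)} meioses x {len(chroms)} chromosomes; "
                "every meiosis x chromosome cell must be present exactly once"
            )

    @property
    def meioses(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for rec in self.records:
            seen.setdefault(rec.meiosis_id, None)
        return tuple(seen)

    @property
    def chromosomes(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for rec in self.records:
            seen.setdefault(rec.chromosome, None)
        return tuple(sorted(seen, key=_chrom_order))

    def sex_of(self, meiosis_id: str) -> str:
        for rec in self.records:
            if rec.meiosis_id == meiosis_id:
                return rec.sex
        raise KeyError(meiosis_id)

    @property
    def n_crossovers(self) -> int:
        return sum(r.n_crossovers for r in self.records)

    def events(self) -> Iterator[CrossoverEvent]:
        """Iterate over individual crossover events, map order."""
        for rec in self.records:
            for pos in rec.positions:
                yield CrossoverEvent(rec.meiosis_id, rec.sex, rec.chromosome, float(pos))

    def to_frame(self) -> pd.DataFrame:
        """Canonical long table: one row per crossover, plus one row with
        position NA for each non-recombinant chromosome (so the full cell
        universe round-trips)."""
        rows = []
        for rec in sorted(
            self.records, key=lambda r: (r.meiosis_id, _chrom_order(r.chromosome))
        ):
            if rec.n_crossovers == 0:
                rows.append(
                    {
                        "meiosis_id": rec.meiosis_id,
                        "sex": rec.sex,
                        "chromosome": rec.chromosome,
                        "position_cM": np.nan,
                    }
                )
            else:
                for pos in rec.positions:
                    rows.append(
                        {
                            "meiosis_id": rec.meiosis_id,
                            "sex": rec.sex,
                            "chromosome": rec.chromosome,
                            "position_cM": float(pos),
                        }
                    )
        return pd.DataFrame(rows, columns=["meiosis_id", "sex", "chromosome", "position_cM"])

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6f")

    @classmethod
    def from_tsv(cls, path, map_table: GeneticMapTable) -> "CrossoverDataset":
        return read_crossover_table(path, map_table)


def _empty_cell_records(
    meiosis_sex: Mapping[str, str],
    chromosomes: Sequence[str],
    map_table: GeneticMapTable,
    filled: Mapping[tuple[str, str], TransmittedChromosome],
) -> list[TransmittedChromosome]:
    records = []
    for mid, sex in meiosis_sex.items():
        for chrom in chromosomes:
            key = (mid, chrom)
            if key in filled:
                records.append(filled[key])
            else:
                records.append(
                    TransmittedChromosome(
                        mid, sex, chrom, map_table.length(chrom, sex), np.empty(0)
                    )
                )
    return records


def read_crossover_table(
    path_or_frame,
    map_table: GeneticMapTable,
    column_map: Mapping[str, str] | None = None,
    meioses: Mapping[str, str] | None = None,
    meiosis_whitelist: Iterable[str] | None = None,
    include_x: bool = False,
) -> CrossoverDataset:
    """Read a crossover table (one row per crossover) into a dataset.

    Parameters
    ----------
    path_or_frame
        Tab-separated file with a header, or an equivalent DataFrame.
    column_map
        Optional mapping from the canonical names
        ``{meiosis_id, sex, chromosome, position_cM}`` to the file's names.
    meioses
        Optional declared universe ``meiosis_id -> sex``. Meioses declared
        here but absent from the file become all-non-recombinant; without
        it the universe is inferred from the file.
    meiosis_whitelist
        Restrict to these meioses (e.g. the fully observed ones).
    include_x
        Keep X-chromosome rows (female meioses only). Off by default:
        the main analysis is autosomal.
    """
    if isinstance(path_or_frame, pd.DataFrame):
        df = path_or_frame.copy()
    else:
        df = pd.read_csv(path_or_frame, sep="\t", dtype=str)
    if column_map:
        df = df.rename(columns={v: k for k, v in column_map.items()})
    required = {"meiosis_id", "sex", "chromosome", "position_cM"}
    if not required.issubset(df.columns):
        raise DataValidationError(
            f"crossover table must have columns {sorted(required)} "
            f"(after remapping); got {list(df.columns)}"
        )
    df = df.astype({"meiosis_id": str, "sex": str, "chromosome": str})
    df["position_cM"] = pd.to_numeric(df["position_cM"], errors="coerce")

    bad_sex = set(df["sex"]) - set(SEXES)
    if bad_sex:
        raise DataValidationError(f"unknown sex codes {sorted(bad_sex)}")

    if meiosis_whitelist is not None:
        allowed = set(meiosis_whitelist)
        df = df[df["meiosis_id"].isin(allowed)]

    if not include_x:
        df = df[df["chromosome"] != "X"]
    else:
        x_male = df[(df["chromosome"] == "X") & (df["sex"] == "M")]
        if len(x_male):
            raise DataValidationError(
                "X-chromosome crossovers in male meioses are not supported"
            )

    known = set(map_table.chromosomes)
    bad_chrom = set(df["chromosome"]) - known
    if bad_chrom:
        raise DataValidationError(
            f"chromosomes {sorted(bad_chrom)} have no entry in the map table"
        )

    meiosis_sex: dict[str, str] = {}
    if meioses is not None:
        meiosis_sex.update({str(k): str(v) for k, v in meioses.items()})
    for row in df.itertuples(index=False):
        prev = meiosis_sex.get(row.meiosis_id)
        if prev is not None and prev != row.sex:
            raise DataValidationError(
                f"meiosis {row.meiosis_id} appears with conflicting sexes"
            )
        meiosis_sex[row.meiosis_id] = row.sex

    chromosomes = sorted(
        set(map_table.chromosomes) - ({"X"} if not include_x else set()),
        key=_chrom_order,
    )

    filled: dict[tuple[str, str], TransmittedChromosome] = {}
    rows_with_pos = df.dropna(subset=["position_cM"])
    for (mid, chrom), grp in rows_with_pos.groupby(["meiosis_id", "chromosome"], sort=True):
        sex = meiosis_sex[mid]
        L = map_table.length(chrom, sex)
        pos = np.sort(grp["position_cM"].to_numpy(dtype=float))
        if pos.size and (pos[0] < 0 or pos[-1] > L):
            raise DataValidationError(
                f"crossover position outside [0, {L}] cM for meiosis {mid}, "
                f"chromosome {chrom}"
            )
        filled[(mid, chrom)] = TransmittedChromosome(mid, sex, chrom, L, pos)

    records = _empty_cell_records(meiosis_sex, chromosomes, map_table, filled)
    return CrossoverDataset(records, map_table)


def segments_to_crossovers(
    path_or_frame,
    map_table: GeneticMapTable,
    column_map: Mapping[str, str] | None = None,
    slack_cM: float = 0.01,
    meioses: Mapping[str, str] | None = None,
    include_x: bool = False,
) -> CrossoverDataset:
    """Convert a haplotype-segment table to crossover events.

    Per (meiosis, chromosome), k contiguous segments spanning [0, L] yield
    k-1 crossovers, one at each junction between adjacent segments. When
    genotyping leaves a gap between the end of one segment and the start of
    the next, the crossover is placed at the midpoint of that boundary
    interval. Gaps or overlaps larger than ``slack_cM`` are data errors.
    """
    if isinstance(path_or_frame, pd.DataFrame):
        df = path_or_frame.copy()
    else:
        df = pd.read_csv(path_or_frame, sep="\t", dtype=str)
    if column_map:
        df = df.rename(columns={v: k for k, v in column_map.items()})
    required = {"meiosis_id", "sex", "chromosome", "start_cM", "end_cM", "haplotype"}
    if not required.issubset(df.columns):
        raise DataValidationError(
            f"segment table must have columns {sorted(required)}; got {list(df.columns)}"
        )
    df = df.astype({"meiosis_id": str, "sex": str, "chromosome": str, "haplotype": str})
    df["start_cM"] = pd.to_numeric(df["start_cM"])
    df["end_cM"] = pd.to_numeric(df["end_cM"])

    if not include_x:
        df = df[df["chromosome"] != "X"]

    meiosis_sex: dict[str, str] = dict(meioses or {})
    crossover_rows = []
    for (mid, chrom), grp in df.groupby(["meiosis_id", "chromosome"], sort=True):
        sex = grp["sex"].iloc[0]
        meiosis_sex[mid] = sex
        L = map_table.length(chrom, sex)
        grp = grp.sort_values("start_cM")
        starts = grp["start_cM"].to_numpy()
        ends = grp["end_cM"].to_numpy()
        haps = grp["haplotype"].to_numpy()
        if abs(starts[0] - 0.0) > slack_cM or abs(ends[-1] - L) > slack_cM:
            raise DataValidationError(
                f"segments for meiosis {mid}, chromosome {chrom} do not span "
                f"[0, {L}] cM"
            )
        for a in range(len(grp) - 1):
            gap = starts[a + 1] - ends[a]
            if abs(gap) > slack_cM:
                kind = "gap" if gap > 0 else "overlap"
                raise DataValidationError(
                    f"{kind} of {abs(gap):.4f} cM between segments for "
                    f"meiosis {mid}, chromosome {chrom}"
                )
            if haps[a + 1] == haps[a]:
                raise DataValidationError(
                    f"adjacent segments with identical haplotype {haps[a]!r} for "
                    f"meiosis {mid}, chromosome {chrom}"
                )
            junction = 0.5 * (ends[a] + starts[a + 1])
            crossover_rows.append(
                {
                    "meiosis_id": mid,
                    "sex": sex,
                    "chromosome": chrom,
                    "position_cM": float(np.clip(junction, 0.0, L)),
                }
            )
    xo = pd.DataFrame(
        crossover_rows, columns=["meiosis_id", "sex", "chromosome", "position_cM"]
    )
    return read_crossover_table(
        xo, map_table, meioses=meiosis_sex, include_x=include_x
    )


@dataclass
class GroupScheme:
    """Assignment of meioses to groups i=1..m and chromosomes to groups
    j=1..n (1-based labels, 0-based indices internally)."""

    meiosis_group: dict[str, int]
    chromosome_group: dict[str, int]
    meiosis_labels: tuple[str, ...]
    chromosome_labels: tuple[str, ...]
    name: str = "custom"

    @property
    def m(self) -> int:
        return len(self.meiosis_labels)

    @property
    def n(self) -> int:
        return len(self.chromosome_labels)

    def cell_of(self, rec: TransmittedChromosome) -> tuple[int, int]:
        return (self.meiosis_group[rec.meiosis_id], self.chromosome_group[rec.chromosome])


def assign_groups(
    data: CrossoverDataset,
    scheme_name: str = "by_sex",
    custom: tuple[Mapping[str, int], Mapping[str, int], Sequence[str], Sequence[str]] | None = None,
) -> GroupScheme:
    """Build a :class:`GroupScheme` for a dataset.

    ``by_sex``: meioses grouped F/M (m=2), all chromosomes pooled (n=1).
    ``by_sex_and_size``: chromosomes additionally binned long (1-5),
    medium (6-12), short (13-19).
    ``by_sex_and_chromosome``: one chromosome group per chromosome.
    ``custom``: user-supplied mappings.
    """
    sex_group = {"F": 0, "M": 1}
    meiosis_group = {mid: sex_group[data.sex_of(mid)] for mid in data.meioses}
    chroms = data.chromosomes
    if scheme_name == "by_sex":
        return GroupScheme(
            meiosis_group, {c: 0 for c in chroms}, ("F", "M"), ("all",), "by_sex"
        )
    if scheme_name == "by_sex_and_size":
        bin_of = {}
        labels = tuple(SIZE_BINS)
        for jdx, (label, members) in enumerate(SIZE_BINS.items()):
            for c in members:
                bin_of[c] = jdx
        missing = [c for c in chroms if c not in bin_of]
        if missing:
            raise DataValidationError(
                f"chromosomes {missing} not covered by the size bins"
            )
        return GroupScheme(
            meiosis_group, {c: bin_of[c] for c in chroms}, ("F", "M"), labels,
            "by_sex_and_size",
        )
    if scheme_name == "by_sex_and_chromosome":
        return GroupScheme(
            meiosis_group,
            {c: j for j, c in enumerate(chroms)},
            ("F", "M"),
            tuple(chroms),
            "by_sex_and_chromosome",
        )
    if scheme_name == "custom":
        if custom is None:
            raise DataValidationError("custom scheme requires explicit mappings")
        mg, cg, mlabels, clabels = custom
        missing = [c for c in chroms if c not in cg]
        if missing:
            raise DataValidationError(
                f"chromosomes {missing} not covered by the custom mapping"
            )
        missing_m = [mid for mid in data.meioses if mid not in mg]
        if missing_m:
            raise DataValidationError(
                f"meioses {missing_m[:5]}... not covered by the custom mapping"
            )
        return GroupScheme(dict(mg), dict(cg), tuple(mlabels), tuple(clabels), "custom")
    raise DataValidationError(f"unknown grouping scheme {scheme_name!r}")


@dataclass
class DescriptiveStats:
    """Descriptive summary of a crossover dataset."""

    n_meioses: int
    n_meioses_by_sex: dict[str, int]
    n_records: int
    total_crossovers: int
    crossovers_by_sex: dict[str, int]
    mean_crossovers_per_meiosis_by_sex: dict[str, float]
    class_counts: dict[str, int]  # keys "0", "1", "2+"
    class_fractions: dict[str, float]
    intercrossover_mean_cM: dict[str, float]
    intercrossover_sd_cM: dict[str, float]

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.__dict__, indent=2, **kwargs)

    def __str__(self) -> str:
        lines = [
            f"meioses: {self.n_meioses} "
            + " ".join(f"{s}={c}" for s, c in self.n_meioses_by_sex.items()),
            f"transmitted chromosomes: {self.n_records}",
            f"crossovers: {self.total_crossovers} "
            + " ".join(f"{s}={c}" for s, c in self.crossovers_by_sex.items()),
            "crossovers per meiosis: "
            + " ".join(
                f"{s}={v:.1f}" for s, v in self.mean_crossovers_per_meiosis_by_sex.items()
            ),
            "chromosomes with 0/1/2+ crossovers: "
            + " / ".join(
                f"{self.class_counts[k]} ({100 * self.class_fractions[k]:.1f}%)"
                for k in ("0", "1", "2+")
            ),
            "inter-crossover distance (cM): "
            + " ".join(
                f"{s}: {self.intercrossover_mean_cM[s]:.1f} "
                f"(SD {self.intercrossover_sd_cM[s]:.1f})"
                for s in self.intercrossover_mean_cM
            ),
        ]
        return "\n".join(lines)


def compute_descriptives(data: CrossoverDataset) -> DescriptiveStats:
    """Counts, per-sex means, the 0/1/2+ recombination classes, and
    inter-crossover distances (chromosomes with >= 2 crossovers only)."""
    by_sex_counts = {s: 0 for s in SEXES}
    meioses_by_sex: dict[str, set] = {s: set() for s in SEXES}
    classes = {"0": 0, "1": 0, "2+": 0}
    distances: dict[str, list] = {s: [] for s in SEXES}
    for rec in data.records:
        n = rec.n_crossovers
        by_sex_counts[rec.sex] += n
        meioses_by_sex[rec.sex].add(rec.meiosis_id)
        classes["0" if n == 0 else "1" if n == 1 else "2+"] += 1
        if n >= 2:
            distances[rec.sex].extend(np.diff(rec.positions).tolist())
    n_records = len(data.records)
    total = sum(by_sex_counts.values())
    mean_per_meiosis = {
        s: (by_sex_counts[s] / len(meioses_by_sex[s]) if meioses_by_sex[s] else float("nan"))
        for s in SEXES
    }
    inter_mean = {}
    inter_sd = {}
    for s in SEXES:
        d = np.asarray(distances[s])
        inter_mean[s] = float(d.mean()) if d.size else float("nan")
        inter_sd[s] = float(d.std(ddof=1)) if d.size > 1 else float("nan")
    return DescriptiveStats(
        n_meioses=sum(len(v) for v in meioses_by_sex.values()),
        n_meioses_by_sex={s: len(meioses_by_sex[s]) for s in SEXES},
        n_records=n_records,
        total_crossovers=total,
        crossovers_by_sex=dict(by_sex_counts),
        mean_crossovers_per_meiosis_by_sex=mean_per_meiosis,
        class_counts=classes,
        class_fractions={k: (v / n_records if n_records else float("nan")) for k, v in classes.items()},
        intercrossover_mean_cM=inter_mean,
        intercrossover_sd_cM=inter_sd,
    )
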