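"""Marker maps and per-individual genotype vectors for a two-parent cross.

The detection system is a semidwarf hybrid rice screen: two parents each
carry a different defective allele of the growth gene *SD1*, so a mitotic
crossover (CO) or gene conversion (GC) between the two haplotypes in an F1
can restore a functional allele and a tall phenotype.  Genotypes at each
marker are coded relative to the named parents:

* ``N`` -- homozygous for the 93-11-like allele,
* ``P`` -- homozygous for the PA64s-like allele,
* ``H`` -- heterozygous,
* ``NA`` -- missing call.

Two intragenic diagnostic markers (the "focal" pair, M8/M9 in the standard
15-marker layout, ~2.3 kb apart) sit inside the gene: one tags the
383-bp deletion carried by the P haplotype, the other the premature-stop
substitution carried by the N haplotype.  The state pair at those two
markers decides whether an individual carries a restored haplotype.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

#: genotype state symbols
N = "N"
P = "P"
H = "H"
MISSING = "NA"

STATES = (N, P, H)
ALL_STATES = STATES + (MISSING,)
HOMOZYGOUS = (N, P)

_MAP_COLUMNS = ["marker_id", "chrom", "pos_bp", "allele_N", "allele_P"]
_GENO_COLUMNS = ["sample_id", "marker_id", "state"]


class MarkerMapError(ValueError):
    """Malformed or inconsistent marker map."""


class GenotypeError(ValueError):
    """Malformed genotype table or state symbol."""


class FocalMarkerMissing(GenotypeError):
    """An individual lacks a call at one of the two intragenic markers.

    Such individuals cannot be screened for a restored haplotype and are
    excluded from event calling.
    """


@dataclass(frozen=True)
class MarkerMap:
    """Ordered, validated marker map on a single chromosome.

    Positions are 1-based base pairs and strictly increasing; every marker
    is informative (parental alleles differ).  ``focal_markers`` holds the
    0-based indices of the two intragenic diagnostic markers
    (deletion-site marker first, stop-site marker second).
    """

    marker_id: tuple[str, ...]
    chromosome: str
    position: tuple[int, ...]
    allele_n: tuple[str, ...]
    allele_p: tuple[str, ...]
    focal_markers: tuple[int, int]

    def __post_init__(self) -> None:
        n = len(self.marker_id)
        if n < 2:
            raise MarkerMapError("marker map needs at least 2 markers")
        if not (len(self.position) == len(self.allele_n) == len(self.allele_p) == n):
            raise MarkerMapError("marker map columns have unequal lengths")
        for i in range(1, n):
            if self.position[i] <= self.position[i - 1]:
                raise MarkerMapError(
                    f"positions not strictly increasing at marker "
                    f"{self.marker_id[i]} ({self.position[i - 1]} -> {self.position[i]})"
                )
        for i, (a, b) in enumerate(zip(self.allele_n, self.allele_p)):
            if a == b:
                raise MarkerMapError(
                    f"marker {self.marker_id[i]} is uninformative: "
                    f"identical parental alleles {a!r}"
                )
        i, j = self.focal_markers
        if not (0 <= i < n and 0 <= j < n) or i >= j:
            raise MarkerMapError(f"invalid focal marker indices {self.focal_markers}")

    @property
    def n_markers(self) -> int:
        return len(self.marker_id)

    @property
    def span(self) -> int:
        """Distance in bp from the first to the last marker."""
        return self.position[-1] - self.position[0]

    @property
    def focal_distance(self) -> int:
        i, j = self.focal_markers
        return self.position[j] - self.position[i]

    def index(self, marker_id: str) -> int:
        try:
            return self.marker_id.index(marker_id)
        except ValueError:
            raise MarkerMapError(f"unknown marker id {marker_id!r}") from None


@dataclass(frozen=True)
class GenotypeVector:
    """One individual's ordered genotype states over a marker map."""

    sample_id: str
    states: tuple[str, ...]

    def __post_init__(self) -> None:
        for s in self.states:
            if s not in ALL_STATES:
                raise GenotypeError(
                    f"sample {self.sample_id!r}: state {s!r} not in {ALL_STATES}"
                )

    @property
    def n_markers(self) -> int:
        return len(self.states)

    def missing_indices(self) -> frozenset[int]:
        return frozenset(i for i, s in enumerate(self.states) if s == MISSING)


@dataclass(frozen=True)
class Sd1AlleleModel:
    """Location of the two defective-allele diagnostic sites.

    ``del_marker`` indexes the deletion site (defect on the P haplotype),
    ``stop_marker`` the premature-stop site (defect on the N haplotype).
    """

    del_marker: int
    stop_marker: int

    def __post_init__(self) -> None:
        if self.del_marker == self.stop_marker:
            raise MarkerMapError("deletion and stop sites must differ")
        if self.del_marker < 0 or self.stop_marker < 0:
            raise MarkerMapError("focal marker indices must be non-negative")

    @classmethod
    def from_map(cls, mmap: MarkerMap) -> "Sd1AlleleModel":
        i, j = mmap.focal_markers
        return cls(del_marker=i, stop_marker=j)


#: state pairs (deletion site, stop site) diagnostic of a restored haplotype
RESTORED_STATE_PAIRS = frozenset({(N, P), (N, H), (H, P)})


def _default_focal(n: int) -> tuple[int, int]:
    # central adjacent pair; yields indices (7, 8) == M8/M9 on a 15-marker map
    return (n // 2, n // 2 + 1) if n // 2 + 1 < n else (n - 2, n - 1)


def read_marker_map(path: str | Path, focal_markers: tuple[int, int] | None = None) -> MarkerMap:
    """Read a marker map TSV (columns marker_id, chrom, pos_bp, allele_N, allele_P).

    ``#`` comment lines are permitted; a ``# focal_markers: Mi,Mj`` comment
    designates the intragenic pair by marker id and takes precedence over
    the default (the central adjacent pair) but not over the
    ``focal_markers`` argument.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    focal_ids: tuple[str, str] | None = None
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") and "focal_markers:" in line:
                names = line.split("focal_markers:", 1)[1].strip().replace(",", " ").split()
                if len(names) == 2:
                    focal_ids = (names[0], names[1])
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"marker_id": str})
    missing_cols = [c for c in _MAP_COLUMNS if c not in df.columns]
    if missing_cols:
        raise MarkerMapError(f"marker map missing columns: {missing_cols}")
    chroms = df["chrom"].unique()
    if len(chroms) != 1:
        raise MarkerMapError(f"expected a single chromosome, got {list(chroms)}")
    ids = tuple(df["marker_id"].astype(str))
    if focal_markers is None:
        if focal_ids is not None:
            focal_markers = (ids.index(focal_ids[0]), ids.index(focal_ids[1]))
        else:
            focal_markers = _default_focal(len(ids))
    return MarkerMap(
        marker_id=ids,
        chromosome=str(chroms[0]),
        position=tuple(int(p) for p in df["pos_bp"]),
        allele_n=tuple(str(a) for a in df["allele_N"]),
        allele_p=tuple(str(a) for a in df["allele_P"]),
        focal_markers=focal_markers,
    )


def write_marker_map(mmap: MarkerMap, path: str | Path) -> None:
    """Write a marker map TSV; the focal pair is recorded as a comment."""
    path = Path(path)
    i, j = mmap.focal_markers
    with open(path, "w") as fh:
        fh.write(f"# focal_markers: {mmap.marker_id[i]},{mmap.marker_id[j]}\n")
        fh.write("\t".join(_MAP_COLUMNS) + "\n")
        for k in range(mmap.n_markers):
            fh.write(
                f"{mmap.marker_id[k]}\t{mmap.chromosome}\t{mmap.position[k]}"
                f"\t{mmap.allele_n[k]}\t{mmap.allele_p[k]}\n"
            )


def read_genotypes(path: str | Path, mmap: MarkerMap) -> list[GenotypeVector]:
    """Read a long-format genotype TSV (sample_id, marker_id, state).

    Returns one vector per sample in order of first appearance; (sample,
    marker) pairs absent from the table become ``NA``.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing_cols = [c for c in _GENO_COLUMNS if c not in df.columns]
    if missing_cols:
        raise GenotypeError(f"genotype table missing columns: {missing_cols}")
    marker_index = {m: i for i, m in enumerate(mmap.marker_id)}
    vectors: dict[str, list[str]] = {}
    seen: set[tuple[str, str]] = set()
    for sample, marker, state in df[_GENO_COLUMNS].itertuples(index=False):
        if marker not in marker_index:
            raise GenotypeError(f"unknown marker id {marker!r} for sample {sample!r}")
        if state not in ALL_STATES:
            raise GenotypeError(
                f"sample {sample!r}, marker {marker!r}: state {state!r} "
                f"not in {ALL_STATES}"
            )
        key = (sample, marker)
        if key in seen:
            raise GenotypeError(f"duplicate genotype row for {key}")
        seen.add(key)
        vectors.setdefault(sample, [MISSING] * mmap.n_markers)[marker_index[marker]] = state
    return [GenotypeVector(sample_id=s, states=tuple(v)) for s, v in vectors.items()]


def write_genotypes(
    vectors: Iterable[GenotypeVector], mmap: MarkerMap, path: str | Path
) -> None:
    """Write vectors in long format; missing states are omitted (they read
    back as ``NA``)."""
    with open(path, "w") as fh:
        fh.write("\t".join(_GENO_COLUMNS) + "\n")
        for gv in vectors:
            if gv.n_markers != mmap.n_markers:
                raise GenotypeError(
                    f"sample {gv.sample_id!r} has {gv.n_markers} states for a "
                    f"{mmap.n_markers}-marker map"
                )
            for marker, state in zip(mmap.marker_id, gv.states):
                if state != MISSING:
                    fh.write(f"{gv.sample_id}\t{marker}\t{state}\n")


def sd1_restored(gv: GenotypeVector, model: Sd1AlleleModel) -> tuple[bool, str | None]:
    """Decide whether an individual carries a restored (wild-type) haplotype.

    The diagnostic is the state pair at the (deletion-site, stop-site)
    markers: exactly the three switched pairs (N,P), (N,H) and (H,P)
    indicate a restored haplotype.  (H,H) is the nonrecombinant F1 and the
    parental pairs are homozygous defectives; all return False.

    Returns ``(restored, class_label)`` where the label names the state
    pair with 1-based marker numbers (e.g. ``"H8-P9"``).  Raises
    :class:`FocalMarkerMissing` if either diagnostic call is absent.
    """
    s_del = gv.states[model.del_marker]
    s_stop = gv.states[model.stop_marker]
    if MISSING in (s_del, s_stop):
        raise FocalMarkerMissing(
            f"sample {gv.sample_id!r}: missing call at a focal marker; "
            "individual excluded from event calling"
        )
    restored = (s_del, s_stop) in RESTORED_STATE_PAIRS
    label = f"{s_del}{model.del_marker + 1}-{s_stop}{model.stop_marker + 1}" if restored else None
    return restored, label
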