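"""Core data model: alignments, population maps, fragment layouts, haplotype tables.

Coordinates are 1-based inclusive throughout, matching the convention used for
reporting polymorphic-site positions on the sequenced fragment; even after a
region is extracted, site positions are reported in original-fragment
coordinates via the column map returned by :func:`extract_region`.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

ALPHABET = frozenset("ACGT-N")
MISSING = frozenset("-N")


class AlignmentShapeError(ValueError):
    """Raised when input sequences are ragged (not all of equal length)."""


class AlphabetError(ValueError):
    """Raised when a sequence contains a character outside {A,C,G,T,-,N}."""


class PopmapSchemaError(ValueError):
    """Raised on malformed population-map tables (columns, duplicates)."""


class MappingError(KeyError):
    """Raised when a sample has no population assignment."""


class EmptyRegionError(ValueError):
    """Raised when a region extraction selects no columns."""


@dataclass
class Alignment:
    """A haploid multiple sequence alignment.

    Parameters
    ----------
    ids
        Unique, non-empty sample identifiers, in input order.
    seqs
        Equal-length DNA strings over ``{A,C,G,T,-,N}`` (upper-cased on
        construction).
    """

    ids: list[str]
    seqs: list[str]

    def __post_init__(self) -> None:
        self.seqs = [s.upper() for s in self.seqs]
        if len(self.ids) != len(self.seqs):
            raise AlignmentShapeError("ids and seqs differ in length")
        if any(not i for i in self.ids):
            raise ValueError("empty sample id")
        if len(set(self.ids)) != len(self.ids):
            dup = [i for i in self.ids if self.ids.count(i) > 1]
            raise ValueError(f"duplicate sample ids: {sorted(set(dup))}")
        if self.seqs:
            L = len(self.seqs[0])
            for sid, s in zip(self.ids, self.seqs):
                if len(s) != L:
                    raise AlignmentShapeError(
                        f"record {sid!r} has length {len(s)}, expected {L}"
                    )
                bad = set(s) - ALPHABET
                if bad:
                    pos = next(k for k, c in enumerate(s) if c in bad)
                    raise AlphabetError(
                        f"record {sid!r}: illegal character {s[pos]!r} at column {pos + 1}"
                    )

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def length(self) -> int:
        return len(self.seqs[0]) if self.seqs else 0

    def to_array(self) -> np.ndarray:
        """Return the alignment as an ``(n, L)`` byte array (dtype ``S1``)."""
        return np.frombuffer("".join(self.seqs).encode(), dtype="S1").reshape(
            self.n, self.length
        )

    def subset(self, ids: Sequence[str]) -> "Alignment":
        """Row subset preserving the order given in *ids*."""
        idx = {s: k for k, s in enumerate(self.ids)}
        missing = [s for s in ids if s not in idx]
        if missing:
            raise MappingError(f"samples not in alignment: {missing}")
        return Alignment([s for s in ids], [self.seqs[idx[s]] for s in ids])


@dataclass
class PopulationSet:
    """Sample → population assignment with optional site coordinates/regions."""

    sample_to_pop: dict[str, str]
    pop_coords: dict[str, tuple[float, float]] = field(default_factory=dict)
    pop_region: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for pop, (lat, lon) in self.pop_coords.items():
            if not -90.0 <= lat <= 90.0:
                raise ValueError(f"latitude {lat} out of range for {pop}")
            if not -180.0 <= lon <= 180.0:
                raise ValueError(f"longitude {lon} out of range for {pop}")

    @property
    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.sample_to_pop.values():
            seen.setdefault(p)
        return list(seen)

    def samples_of(self, pop: str) -> list[str]:
        return [s for s, p in self.sample_to_pop.items() if p == pop]

    def require_coords(self) -> None:
        missing = [p for p in self.populations if p not in self.pop_coords]
        if missing:
            raise MappingError(f"populations without coordinates: {missing}")


@dataclass
class FragmentLayout:
    """Exon/intron tiling of the sequenced fragment plus the focal codon span.

    ``segments`` is an ordered list of ``(label, start, end)`` with label in
    {"exon", "intron"}; segments must tile ``[1, length]`` without gaps or
    overlap, and the 3-base codon must sit inside a single exon.
    """

    segments: list[tuple[str, int, int]]
    codon_span: tuple[int, int]

    def __post_init__(self) -> None:
        pos = 1
        for label, start, end in self.segments:
            if label not in ("exon", "intron"):
                raise ValueError(f"unknown segment label {label!r}")
            if start != pos or end < start:
                raise ValueError("segments must tile the fragment contiguously")
            pos = end + 1
        c0, c1 = self.codon_span
        if c1 - c0 != 2:
            raise ValueError("codon span must cover exactly 3 bases")
        if not any(
            lab == "exon" and s <= c0 and c1 <= e for lab, s, e in self.segments
        ):
            raise ValueError("codon span must lie inside one exon segment")

    @property
    def length(self) -> int:
        return self.segments[-1][2]

    def columns(self, labels: Iterable[str]) -> list[int]:
        """1-based columns of all segments whose label is in *labels*."""
        want = set(labels)
        cols: list[int] = []
        for lab, s, e in self.segments:
            if lab in want:
                cols.extend(range(s, e + 1))
        return cols

    def codon_columns(self) -> list[int]:
        c0, c1 = self.codon_span
        return [c0, c0 + 1, c1]

    @classmethod
    def from_json(cls, path: str | Path) -> "FragmentLayout":
        obj = json.loads(Path(path).read_text())
        segs = [(d["label"], int(d["start"]), int(d["end"])) for d in obj["segments"]]
        c = obj["codon"]
        return cls(segs, (int(c[0]), int(c[1])))

    def to_json(self, path: str | Path) -> None:
        obj = {
            "segments": [
                {"label": lab, "start": s, "end": e} for lab, s, e in self.segments
            ],
            "codon": list(self.codon_span),
        }
        Path(path).write_text(json.dumps(obj, indent=1))


def kdr_fragment_layout() -> FragmentLayout:
    """Layout of the 1285 bp sodium-channel fragment around codon L1014.

    Exon(1-74) / intron-1(75-979) / exon(980-1166) / intron-2(1167-1230) /
    exon(1231-1285), with the resistance codon at 1160-1162 — the unique
    arrangement consistent with the published segment lengths
    (74+905+187+64+55) and with the reported intron/codon site positions.
    """
    return FragmentLayout(
        segments=[
            ("exon", 1, 74),
            ("intron", 75, 979),
            ("exon", 980, 1166),
            ("intron", 1167, 1230),
            ("exon", 1231, 1285),
        ],
        codon_span=(1160, 1162),
    )


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_alignment(path: str | Path, format: str = "fasta") -> Alignment:
    """Read an aligned FASTA file into an :class:`Alignment` (input order kept)."""
    if format.lower() != "fasta":
        raise ValueError(f"unsupported alignment format: {format}")
    ids, seqs = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        ids.append(rec.id)
        seqs.append(str(rec.seq))
    if not ids:
        raise ValueError(f"no FASTA records in {path}")
    return Alignment(ids, seqs)


def write_alignment(aln: Alignment, path: str | Path) -> None:
    recs = [
        SeqRecord(Seq(s), id=i, description="") for i, s in zip(aln.ids, aln.seqs)
    ]
    SeqIO.write(recs, str(path), "fasta")


_DEGMIN = re.compile(r"^\s*(\d+(?:\.\d+)?)\s*[°d]\s*(?:(\d+(?:\.\d+)?)\s*['’m]?)?\s*$")


def parse_coordinate(text: str | float) -> float:
    """Parse a coordinate given either as decimal degrees or as deg-min text.

    ``"24°51'"`` → ``24 + 51/60``; plain numbers pass through.
    """
    if isinstance(text, (int, float)) and not isinstance(text, bool):
        return float(text)
    s = str(text).strip()
    try:
        return float(s)
    except ValueError:
        pass
    m = _DEGMIN.match(s)
    if not m:
        raise ValueError(f"cannot parse coordinate {text!r}")
    deg = float(m.group(1))
    minutes = float(m.group(2)) if m.group(2) else 0.0
    return deg + minutes / 60.0


_POPMAP_COLS = {"sample", "population", "latitude", "longitude", "region"}


def read_popmap(path: str | Path) -> PopulationSet:
    """Read a sample→population TSV (columns: sample, population[, latitude,
    longitude, region]) into a :class:`PopulationSet`."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    unknown = set(df.columns) - _POPMAP_COLS
    if unknown:
        raise PopmapSchemaError(f"unknown popmap columns: {sorted(unknown)}")
    for col in ("sample", "population"):
        if col not in df.columns:
            raise PopmapSchemaError(f"popmap missing required column {col!r}")
    if df["sample"].duplicated().any():
        dups = df.loc[df["sample"].duplicated(), "sample"].tolist()
        raise PopmapSchemaError(f"duplicate sample rows: {dups}")
    sample_to_pop = dict(zip(df["sample"], df["population"]))
    pop_coords: dict[str, tuple[float, float]] = {}
    pop_region: dict[str, str] = {}
    for _, row in df.iterrows():
        pop = row["population"]
        lat = row.get("latitude")
        lon = row.get("longitude")
        if isinstance(lat, str) and isinstance(lon, str) and lat and lon:
            coord = (parse_coordinate(lat), parse_coordinate(lon))
            prev = pop_coords.setdefault(pop, coord)
            if not np.allclose(prev, coord):
                raise PopmapSchemaError(
                    f"conflicting coordinates for population {pop!r}"
                )
        reg = row.get("region")
        if isinstance(reg, str) and reg:
            pop_region[pop] = reg
    return PopulationSet(sample_to_pop, pop_coords, pop_region)


def write_popmap(pops: PopulationSet, path: str | Path) -> None:
    rows = []
    for sample, pop in pops.sample_to_pop.items():
        lat, lon = pops.pop_coords.get(pop, (None, None))
        rows.append(
            {
                "sample": sample,
                "population": pop,
                "latitude": lat,
                "longitude": lon,
                "region": pops.pop_region.get(pop, ""),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Region extraction and haplotype collapsing
# ---------------------------------------------------------------------------

def extract_region(
    aln: Alignment, layout: FragmentLayout, labels: Iterable[str]
) -> tuple[Alignment, list[int]]:
    """Restrict *aln* to the columns of segments whose label is in *labels*.

    Returns the column-restricted alignment and the list of original 1-based
    column positions, so downstream site reports can use fragment coordinates.
    """
    if layout.length != aln.length:
        raise ValueError(
            f"layout length {layout.length} != alignment length {aln.length}"
        )
    cols = layout.columns(labels)
    if not cols:
        raise EmptyRegionError(f"no columns selected by labels {sorted(set(labels))}")
    idx = np.asarray(cols, dtype=int) - 1
    arr = aln.to_array()[:, idx]
    seqs = [row.tobytes().decode() for row in arr]
    return Alignment(list(aln.ids), seqs), cols


def extract_columns(aln: Alignment, cols_1based: Sequence[int]) -> Alignment:
    """Restrict *aln* to an explicit list of 1-based columns (order kept)."""
    idx = np.asarray(list(cols_1based), dtype=int) - 1
    arr = aln.to_array()[:, idx]
    return Alignment(list(aln.ids), [row.tobytes().decode() for row in arr])


@dataclass
class HaplotypeTable:
    """Distinct sequences with a haplotype × population count matrix."""

    haplotypes: list[str]
    counts: np.ndarray  # (n_haplotypes, n_populations) int
    populations: list[str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if len(set(self.haplotypes)) != len(self.haplotypes):
            raise ValueError("haplotype strings must be pairwise distinct")
        if self.counts.shape != (len(self.haplotypes), len(self.populations)):
            raise ValueError("counts shape mismatch")
        if (self.counts < 0).any():
            raise ValueError("negative haplotype counts")

    @property
    def total_n(self) -> int:
        return int(self.counts.sum())

    @property
    def n_haplotypes(self) -> int:
        return len(self.haplotypes)

    def pop_sizes(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def frequencies(self) -> np.ndarray:
        """Per-population haplotype frequency matrix (columns sum to 1)."""
        sizes = self.pop_sizes().astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            return self.counts / sizes

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.counts, columns=self.populations)
        df.insert(0, "haplotype", self.haplotypes)
        return df


def collapse_haplotypes(
    aln: Alignment, pops: PopulationSet | Mapping[str, str] | None = None
) -> HaplotypeTable:
    """Collapse identical sequences into a haplotype × population count table.

    Haplotype identity is exact string match (gaps and N are ordinary states);
    haplotype order is first occurrence in the alignment.
    """
    if pops is None:
        mapping = {s: "all" for s in aln.ids}
    elif isinstance(pops, PopulationSet):
        mapping = pops.sample_to_pop
    else:
        mapping = dict(pops)
    missing = [s for s in aln.ids if s not in mapping]
    if missing:
        raise MappingError(f"samples without population: {missing}")
    pop_order: dict[str, int] = {}
    for s in aln.ids:
        pop_order.setdefault(mapping[s], len(pop_order))
    hap_order: dict[str, int] = {}
    for s in aln.seqs:
        hap_order.setdefault(s, len(hap_order))
    counts = np.zeros((len(hap_order), len(pop_order)), dtype=int)
    for sid, seq in zip(aln.ids, aln.seqs):
        counts[hap_order[seq], pop_order[mapping[sid]]] += 1
    return HaplotypeTable(list(hap_order), counts, list(pop_order))
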