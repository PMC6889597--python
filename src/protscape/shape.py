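"""Pentamer-based DNA shape prediction.

DNA shape features — propeller twist (ProT, degrees), minor groove width
(MGW, Angstrom), helix twist (HelT, degrees) and roll (Roll, degrees) — are
structural parameters of the double helix that can be predicted from
sequence alone with a sliding-pentamer lookup: the value assigned to a base
is read off a precomputed table indexed by the 5-mer centred on that base.
ProT and MGW are defined per base pair; HelT and Roll are base-pair-step
parameters, and the per-base value reported here is the mean of the two
central steps of the pentamer (the steps flanking the centre base), which
makes all four features symmetric under reverse complementation.

The engine is table-agnostic: correctness is defined relative to whichever
pentamer table is supplied.  The bundled table
(``data/prot_pentamers_synthetic.tsv``) is a *synthetic* reference asset
generated by :func:`protscape.synth.gen_fixture_table`; it reproduces the
qualitative AT/GC trend of published ProT tables (AT-rich pentamers more
negative) but not their numerical values.
"""

from __future__ import annotations

import gzip
import importlib.resources
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "FEATURES",
    "BASE_CENTERED_FEATURES",
    "ShapeTable",
    "ShapeTrack",
    "reverse_complement",
    "all_pentamers",
    "load_shape_table",
    "load_reference_table",
    "predict_shape",
    "predict_tracks",
    "write_track",
    "read_track",
]

FEATURES = ("ProT", "MGW", "HelT", "Roll")
#: features defined per base pair (value centred on a base, not a step)
BASE_CENTERED_FEATURES = ("ProT", "MGW")

_BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")
_POW4 = (4 ** np.arange(4, -1, -1)).astype(np.int64)

# byte -> base code (A,C,G,T -> 0..3, anything else -> -1)
_CODES = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate(_BASES):
    _CODES[ord(_b)] = _i
    _CODES[ord(_b.lower())] = _i


def reverse_complement(seq: str) -> str:
    """Reverse complement of a nucleotide string (case preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


def _encode(seq: str) -> np.ndarray:
    """Sequence -> int codes, non-ACGT symbols mapped to -1."""
    try:
        raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    except UnicodeEncodeError as exc:
        raise ValueError(f"sequence contains non-ASCII characters: {exc}") from None
    return _CODES[raw]


def _pentamer_index(pentamer: str) -> int:
    codes = _encode(pentamer)
    if len(codes) != 5 or (codes < 0).any():
        raise ValueError(f"malformed pentamer {pentamer!r}: need 5 bases over ACGT")
    return int(codes @ _POW4)


def all_pentamers() -> list[str]:
    """All 1024 pentamers in table index order (AAAAA, AAAAC, ...)."""
    out = []
    for i in range(1024):
        digits = []
        for p in range(4, -1, -1):
            digits.append(_BASES[(i >> (2 * p)) & 3])
        out.append("".join(digits))
    return out


@dataclass(frozen=True)
class ShapeTable:
    """Pentamer -> shape value lookup with reverse-complement symmetry.

    ``values`` is a dense length-1024 array indexed by the base-4 encoding of
    the pentamer (A=0, C=1, G=2, T=3); absent pentamers hold NaN.
    """

    feature: str
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.feature not in FEATURES:
            raise ValueError(f"unknown feature {self.feature!r}; expected one of {FEATURES}")
        v = np.asarray(self.values, dtype=np.float64)
        if v.shape != (1024,):
            raise ValueError("ShapeTable.values must have shape (1024,)")
        object.__setattr__(self, "values", v)

    @classmethod
    def from_entries(cls, entries: Mapping[str, float], feature: str) -> "ShapeTable":
        """Build a table from pentamer->value pairs, closing under reverse
        complementation and rejecting symmetry conflicts.
        """
        if not entries:
            raise ValueError("no entries: shape table is empty")
        values = np.full(1024, np.nan)
        source: dict[int, str] = {}
        for pent, val in entries.items():
            val = float(val)
            if not np.isfinite(val):
                raise ValueError(f"non-finite value for pentamer {pent!r}")
            idx = _pentamer_index(pent)
            rc_idx = _pentamer_index(reverse_complement(pent.upper()))
            for j in (idx, rc_idx):
                if np.isfinite(values[j]) and abs(values[j] - val) > 1e-9:
                    raise ValueError(
                        f"symmetry conflict for {feature}: pentamer {pent!r} -> {val} "
                        f"contradicts earlier entry {source[j]!r} -> {values[j]} "
                        "(reverse-complement pair must share one value)"
                    )
                values[j] = val
                source[j] = pent
        return cls(feature=feature, values=values)

    def __len__(self) -> int:
        return int(np.isfinite(self.values).sum())

    def value(self, pentamer: str) -> float:
        """Table value for one pentamer (NaN if absent)."""
        return float(self.values[_pentamer_index(pentamer)])

    def __contains__(self, pentamer: str) -> bool:
        return np.isfinite(self.values[_pentamer_index(pentamer)])


@dataclass
class ShapeTrack:
    """Per-base shape values for one sequence.

    ``values`` has one entry per base (0-based); undefined positions (the two
    bases at each end, and any base whose pentamer touches a non-ACGT symbol
    or an absent table entry) are NaN, never 0.
    """

    name: str
    feature: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 1:
            raise ValueError("ShapeTrack.values must be one-dimensional")

    def __len__(self) -> int:
        return self.values.shape[0]

    @property
    def defined(self) -> np.ndarray:
        return np.isfinite(self.values)

    @property
    def n_defined(self) -> int:
        return int(self.defined.sum())


def _open_text(path) -> object:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def load_shape_table(path, feature: str = "ProT") -> ShapeTable:
    """Read a tab-delimited pentamer table (columns: pentamer, value).

    Missing reverse complements are filled by symmetry; a reverse-complement
    pair carrying two different values is rejected with the offending row.
    Lines starting with ``#`` and a ``pentamer<TAB>value`` header are skipped.
    """
    entries: dict[str, float] = {}
    rows: dict[str, int] = {}
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if lineno == 1 and fields[0].lower() in ("pentamer", "kmer", "5mer"):
                continue
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected 'pentamer<TAB>value', got {line!r}")
            pent = fields[0].strip().upper()
            try:
                val = float(fields[1])
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-numeric value {fields[1]!r}") from None
            try:
                _pentamer_index(pent)
            except ValueError:
                raise ValueError(f"{path}:{lineno}: malformed pentamer {fields[0]!r}") from None
            if pent in entries and abs(entries[pent] - val) > 1e-9:
                raise ValueError(
                    f"{path}:{lineno}: duplicate pentamer {pent!r} with conflicting value"
                )
            rc = reverse_complement(pent)
            if rc in entries and abs(entries[rc] - val) > 1e-9:
                raise ValueError(
                    f"{path}:{lineno}: symmetry conflict — {pent!r} -> {val} but its "
                    f"reverse complement {rc!r} -> {entries[rc]} (row {rows[rc]})"
                )
            entries[pent] = val
            rows[pent] = lineno
    if not entries:
        raise ValueError(f"{path}: no entries")
    return ShapeTable.from_entries(entries, feature=feature)


def load_reference_table(feature: str = "ProT") -> ShapeTable:
    """Load the bundled synthetic reference pentamer table.

    The asset is generated data (see :func:`protscape.synth.gen_fixture_table`),
    not a published shape table; it carries the correct symmetry and AT/GC
    trend and is intended for simulations, examples and tests.
    """
    ref = importlib.resources.files("protscape").joinpath("data/prot_pentamers_synthetic.tsv")
    with importlib.resources.as_file(ref) as path:
        return load_shape_table(path, feature=feature)


def predict_shape(sequence: str, table: ShapeTable) -> ShapeTrack:
    """Per-base shape track for ``sequence`` via sliding-pentamer lookup.

    Position ``i`` (``2 <= i <= L-3``) gets ``table[sequence[i-2:i+3]]``;
    the first and last two bases, and any position whose pentamer covers a
    non-ACGT symbol, are NaN.  Lowercase input is accepted.
    """
    return ShapeTrack(name="seq", feature=table.feature, values=_predict_values(sequence, table))


def _values_from_codes(codes: np.ndarray, table: "ShapeTable") -> np.ndarray:
    """Sliding-pentamer lookup on an already-encoded sequence (-1 = non-ACGT)."""
    L = len(codes)
    if L < 5:
        raise ValueError(f"sequence length {L} < 5: no pentamer fits")
    values = np.full(L, np.nan)
    # pentamer index for every window, computed only where all 5 codes are valid
    win = np.lib.stride_tricks.sliding_window_view(codes, 5)
    valid = (win >= 0).all(axis=1)
    idx = np.where(valid, win @ _POW4, 0)
    center = np.where(valid, table.values[idx], np.nan)
    values[2 : L - 2] = center
    return values


def _predict_values(sequence: str, table: ShapeTable) -> np.ndarray:
    return _values_from_codes(_encode(sequence), table)


def predict_tracks(sequences: Mapping[str, str], table: ShapeTable) -> dict[str, ShapeTrack]:
    """Predict shape tracks for a registry of named sequences."""
    return {
        name: ShapeTrack(name=name, feature=table.feature, values=_predict_values(seq, table))
        for name, seq in sequences.items()
    }


# ---------------------------------------------------------------------------
# track serialisation (bedGraph / wiggle)
# ---------------------------------------------------------------------------

def _runs(values: np.ndarray) -> Iterable[tuple[int, int, float]]:
    """Maximal runs of identical finite values as (start, end, value)."""
    finite = np.isfinite(values)
    i, L = 0, len(values)
    while i < L:
        if not finite[i]:
            i += 1
            continue
        j = i + 1
        while j < L and finite[j] and values[j] == values[i]:
            j += 1
        yield i, j, float(values[i])
        i = j


def write_track(track: ShapeTrack, path, format: str = "bedGraph") -> None:
    """Write a track as bedGraph (0-based half-open) or variableStep wiggle.

    Missing positions are omitted; consecutive equal values are merged into
    one bedGraph line.  The track line's description records the feature and
    sequence length so that :func:`read_track` can round-trip exactly.
    """
    if format not in ("bedGraph", "wiggle"):
        raise ValueError(f"unknown track format {format!r}")
    L = len(track)
    with open(path, "wt") as fh:
        if format == "bedGraph":
            fh.write(
                f'track type=bedGraph name="{track.name}" '
                f'description="feature={track.feature};length={L}"\n'
            )
            for start, end, val in _runs(track.values):
                fh.write(f"{track.name}\t{start}\t{end}\t{val:.6g}\n")
        else:
            fh.write(
                f'track type=wiggle_0 name="{track.name}" '
                f'description="feature={track.feature};length={L}"\n'
            )
            fh.write(f"variableStep chrom={track.name} span=1\n")
            for pos in np.flatnonzero(track.defined):
                fh.write(f"{pos + 1}\t{track.values[pos]:.6g}\n")  # wiggle is 1-based


def _parse_description(line: str) -> tuple[str, int | None]:
    feature, length = "ProT", None
    if 'description="' in line:
        desc = line.split('description="', 1)[1].split('"', 1)[0]
        for item in desc.split(";"):
            if item.startswith("feature="):
                feature = item.split("=", 1)[1]
            elif item.startswith("length="):
                length = int(item.split("=", 1)[1])
    return feature, length


def read_track(path, length: int | None = None) -> ShapeTrack:
    """Read a track written by :func:`write_track` (bedGraph or wiggle).

    Overlapping or unsorted intervals are rejected.  ``length`` overrides the
    length recorded in the header (needed for files produced elsewhere).
    """
    with _open_text(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise ValueError(f"{path}: empty track file")
    header = lines[0]
    feature, hdr_length = _parse_description(header)
    if length is None:
        length = hdr_length
    name = header.split('name="', 1)[1].split('"', 1)[0] if 'name="' in header else "track"

    if "type=bedGraph" in header:
        rows = []
        for lineno, line in enumerate(lines[1:], start=2):
            f = line.split("\t")
            if len(f) < 4:
                raise ValueError(f"{path}:{lineno}: malformed bedGraph line {line!r}")
            rows.append((f[0], int(f[1]), int(f[2]), float(f[3])))
        last_end = -1
        for chrom, start, end, _ in rows:
            if start < last_end:
                raise ValueError(f"{path}: overlapping or unsorted intervals at {chrom}:{start}")
            if end <= start:
                raise ValueError(f"{path}: empty interval at {chrom}:{start}-{end}")
            last_end = end
        if length is None:
            length = rows[-1][2] if rows else 0
        values = np.full(length, np.nan)
        for chrom, start, end, val in rows:
            name = chrom
            values[start:end] = val
        return ShapeTrack(name=name, feature=feature, values=values)

    if "type=wiggle_0" in header:
        positions, vals = [], []
        for lineno, line in enumerate(lines[1:], start=2):
            if line.startswith(("variableStep", "fixedStep")):
                if "chrom=" in line:
                    name = line.split("chrom=", 1)[1].split()[0]
                continue
            f = line.split()
            positions.append(int(f[0]) - 1)
            vals.append(float(f[1]))
        if positions and any(b <= a for a, b in zip(positions, positions[1:])):
            raise ValueError(f"{path}: unsorted or duplicated wiggle positions")
        if length is None:
            length = (positions[-1] + 1) if positions else 0
        values = np.full(length, np.nan)
        if positions:
            values[np.asarray(positions)] = vals
        return ShapeTrack(name=name, feature=feature, values=values)

    raise ValueError(f"{path}: unrecognised track header {header!r}")
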