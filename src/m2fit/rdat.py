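"""Chemical-mapping dataset container and RDAT / TSV input-output.

The RDAT dialect implemented here is the RMDB text interchange format:
``RDAT_VERSION``, ``NAME``, ``SEQUENCE``, ``OFFSET``, ``SEQPOS``,
``ANNOTATION``, ``ANNOTATION_DATA:k`` and ``REACTIVITY:k`` records, with
mutant identities carried in ``mutation:`` annotation tags.  A plain TSV
dialect (header row = biological positions, first column = variant label) is
accepted for synthetic fixtures.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Variant",
    "ReactivityDataset",
    "RdatFormatError",
    "read_rdat",
    "write_rdat",
    "read_tsv",
    "write_tsv",
    "single_complement_mutants",
    "apply_mutations",
    "COMPLEMENT",
]

COMPLEMENT = {"A": "U", "U": "A", "C": "G", "G": "C"}


class RdatFormatError(ValueError):
    pass


@dataclass(frozen=True)
class Variant:
    """A measured RNA variant: the wild type or a set of substitutions.

    Mutations are (0-based position, wild-type base, mutant base) triples.
    Labels use 1-based biological numbering plus the dataset offset,
    e.g. ``A15U``.
    """

    mutations: tuple[tuple[int, str, str], ...] = ()

    @property
    def is_wildtype(self) -> bool:
        return len(self.mutations) == 0

    def label(self, offset: int = 0) -> str:
        if self.is_wildtype:
            return "WT"
        return ";".join(f"{wt}{pos + 1 + offset}{mut}" for pos, wt, mut in self.mutations)

    @staticmethod
    def from_label(label: str, sequence: str, offset: int = 0) -> "Variant":
        label = label.strip()
        if label.upper() in ("WT", "WILDTYPE", "WILD TYPE", ""):
            return Variant()
        muts = []
        for part in re.split(r"[;,]", label):
            m = re.fullmatch(r"([ACGUT])(-?\d+)([ACGUT])", part.strip(), re.I)
            if m is None:
                raise RdatFormatError(f"cannot parse mutation label {part!r}")
            wt, num, mut = m.group(1).upper(), int(m.group(2)), m.group(3).upper()
            pos = num - 1 - offset
            wt, mut = wt.replace("T", "U"), mut.replace("T", "U")
            if not (0 <= pos < len(sequence)):
                raise RdatFormatError(
                    f"mutation {part!r}: position outside sequence (offset {offset})"
                )
            if sequence[pos].upper() != wt:
                raise RdatFormatError(
                    f"mutation {part!r}: sequence has {sequence[pos]!r} at that position"
                )
            muts.append((pos, wt, mut))
        return Variant(tuple(sorted(muts)))


def apply_mutations(sequence: str, variant: Variant) -> str:
    chars = list(sequence)
    for pos, _wt, mut in variant.mutations:
        chars[pos] = mut
    return "".join(chars)


def single_complement_mutants(sequence: str) -> list[Variant]:
    """One variant per position, mutating each nucleotide to its complement
    (A<->U, C<->G), the variant set typically probed in M2 experiments."""
    out = []
    for i, base in enumerate(sequence.upper()):
        if base not in COMPLEMENT:
            raise ValueError(f"non-ACGU character {base!r} at position {i}")
        out.append(Variant(((i, base, COMPLEMENT[base]),)))
    return out


@dataclass
class ReactivityDataset:
    """An m x n matrix of chemical reactivities with variant descriptors.

    ``reactivities`` holds raw values (background subtraction can produce
    small negatives); ``matrix`` is the nonnegative view used for fitting.
    ``quality_flags[j]`` marks row j low-quality; flagged rows are excluded
    from the default fitting view.  Rows with non-finite entries are flagged
    automatically.
    """

    sequence: str
    reactivities: np.ndarray
    variants: list[Variant]
    modifier: str = ""
    seqpos: np.ndarray | None = None
    offset: int = 0
    quality_flags: np.ndarray | None = None
    name: str = ""
    annotations: list[list[str]] = field(default_factory=list)

    def __post_init__(self):
        self.sequence = self.sequence.upper().replace("T", "U")
        self.reactivities = np.atleast_2d(np.asarray(self.reactivities, dtype=float))
        m, n = self.reactivities.shape
        if m < 1 or n < 2:
            raise ValueError(f"need m >= 1 and n >= 2, got {m} x {n}")
        if len(self.variants) != m:
            raise ValueError(f"{len(self.variants)} variants for {m} rows")
        if self.seqpos is None:
            self.seqpos = np.arange(1, n + 1) + self.offset
        self.seqpos = np.asarray(self.seqpos, dtype=int)
        if len(self.seqpos) != n:
            raise ValueError("seqpos length does not match column count")
        flags = (
            np.zeros(m, dtype=bool)
            if self.quality_flags is None
            else np.asarray(self.quality_flags, dtype=bool).copy()
        )
        flags |= ~np.isfinite(self.reactivities).all(axis=1)
        self.quality_flags = flags
        for v in self.variants:
            for pos, wt, _mut in v.mutations:
                if not (0 <= pos < len(self.sequence)):
                    raise ValueError(f"mutation position {pos} outside sequence")

    @property
    def n_variants(self) -> int:
        return self.reactivities.shape[0]

    @property
    def n_positions(self) -> int:
        return self.reactivities.shape[1]

    @property
    def good_rows(self) -> np.ndarray:
        """Indices of rows not flagged low-quality."""
        return np.flatnonzero(~self.quality_flags)

    @property
    def matrix(self) -> np.ndarray:
        """Good rows only, negatives clamped to 0 (exponential reactivity
        priors have support d >= 0)."""
        sub = self.reactivities[self.good_rows]
        return np.clip(np.nan_to_num(sub, nan=0.0), 0.0, None)

    def column_index(self) -> np.ndarray:
        """Map matrix columns to 0-based sequence positions via seqpos."""
        return self.seqpos - 1 - self.offset

    def wildtype_row(self) -> int:
        """Index of the wild-type row within ``good_rows`` ordering."""
        for k, j in enumerate(self.good_rows):
            if self.variants[j].is_wildtype:
                return k
        raise ValueError("dataset has no usable wild-type row")

    def variant_sequences(self) -> list[str]:
        return [apply_mutations(self.sequence, v) for v in self.variants]


_NUM_RE = re.compile(r"-?\d+")


def _seqpos_token(tok: str) -> int:
    m = _NUM_RE.search(tok)
    if m is None:
        raise RdatFormatError(f"cannot parse SEQPOS token {tok!r}")
    return int(m.group(0))


def read_rdat(path: str | Path) -> ReactivityDataset:
    """Read an RDAT (RMDB dialect) file.

    Tolerates tab- or space-separated records.  Rows annotated with
    ``warning:badQuality`` (or containing non-finite values) are flagged
    low-quality.
    """
    path = Path(path)
    name = ""
    sequence = None
    offset = 0
    seqpos = None
    global_annotations: list[str] = []
    rows: dict[int, np.ndarray] = {}
    row_ann: dict[int, list[str]] = {}

    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t") if "\t" in line else line.split()
        fields = [f for f in (x.strip() for x in fields) if f]
        key, vals = fields[0], fields[1:]
        if key == "RDAT_VERSION" or key == "VERSION":
            continue
        elif key == "NAME":
            name = " ".join(vals)
        elif key == "SEQUENCE":
            sequence = "".join(vals)
        elif key == "OFFSET":
            offset = int(vals[0])
        elif key == "SEQPOS":
            seqpos = np.array([_seqpos_token(t) for t in vals], dtype=int)
        elif key == "ANNOTATION":
            global_annotations.extend(vals)
        elif key.startswith("ANNOTATION_DATA"):
            idx = int(key.split(":")[1])
            row_ann.setdefault(idx, []).extend(vals)
        elif key.startswith("REACTIVITY_ERROR"):
            continue
        elif key.startswith("REACTIVITY"):
            idx = int(key.split(":")[1])
            try:
                rows[idx] = np.array([float(v) for v in vals])
            except ValueError as e:
                raise RdatFormatError(f"bad reactivity value in record {key}: {e}")
        # other record types (COMMENT, STRUCTURE, ...) are ignored

    if sequence is None:
        raise RdatFormatError(f"{path}: missing SEQUENCE record")
    if seqpos is None:
        raise RdatFormatError(f"{path}: missing SEQPOS record")
    if not rows:
        raise RdatFormatError(f"{path}: no REACTIVITY records")
    n = len(seqpos)
    order = sorted(rows)
    for idx in order:
        if len(rows[idx]) != n:
            raise RdatFormatError(
                f"{path}: REACTIVITY:{idx} has {len(rows[idx])} values, "
                f"SEQPOS has {n}"
            )

    sequence = sequence.upper().replace("T", "U")
    modifier = ""
    for ann in global_annotations:
        if ann.lower().startswith("modifier:"):
            modifier = ann.split(":", 1)[1]

    variants, flags, anns = [], [], []
    for idx in order:
        tags = row_ann.get(idx, [])
        anns.append(tags)
        mut_labels = [t.split(":", 1)[1] for t in tags if t.lower().startswith("mutation:")]
        mut_labels = [m for m in mut_labels if m.upper() not in ("WT", "WILDTYPE")]
        if mut_labels:
            variants.append(Variant.from_label(";".join(mut_labels), sequence, offset))
        else:
            variants.append(Variant())
        flags.append(any("badquality" in t.lower() for t in tags))

    return ReactivityDataset(
        sequence=sequence,
        reactivities=np.vstack([rows[i] for i in order]),
        variants=variants,
        modifier=modifier,
        seqpos=seqpos,
        offset=offset,
        quality_flags=np.array(flags),
        name=name,
        annotations=anns,
    )


def write_rdat(path: str | Path, ds: ReactivityDataset) -> None:
    """Write the dataset in the RDAT dialect (tab-separated)."""
    lines = ["RDAT_VERSION\t0.34"]
    if ds.name:
        lines.append(f"NAME\t{ds.name}")
    lines.append(f"SEQUENCE\t{ds.sequence}")
    if ds.offset:
        lines.append(f"OFFSET\t{ds.offset}")
    toks = []
    for p in ds.seqpos:
        i = p - 1 - ds.offset
        base = ds.sequence[i] if 0 <= i < len(ds.sequence) else "N"
        toks.append(f"{base}{p}")
    lines.append("SEQPOS\t" + "\t".join(toks))
    if ds.modifier:
        lines.append(f"ANNOTATION\tmodifier:{ds.modifier}")
    for j in range(ds.n_variants):
        tags = [f"mutation:{ds.variants[j].label(ds.offset)}"]
        if ds.quality_flags[j]:
            tags.append("warning:badQuality")
        lines.append(f"ANNOTATION_DATA:{j + 1}\t" + "\t".join(tags))
    for j in range(ds.n_variants):
        vals = "\t".join(f"{v:.6f}" for v in ds.reactivities[j])
        lines.append(f"REACTIVITY:{j + 1}\t{vals}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_tsv(path: str | Path, sequence: str, modifier: str = "") -> ReactivityDataset:
    """Plain TSV dialect: header row = biological positions, first column =
    variant label (``WT`` or e.g. ``A15U``)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    seqpos = np.array([int(c) for c in df.columns])
    variants = [Variant.from_label(str(lbl), sequence) for lbl in df.index]
    return ReactivityDataset(
        sequence=sequence,
        reactivities=df.to_numpy(dtype=float),
        variants=variants,
        modifier=modifier,
        seqpos=seqpos,
    )


def write_tsv(path: str | Path, ds: ReactivityDataset) -> None:
    df = pd.DataFrame(
        ds.reactivities,
        index=[v.label(ds.offset) for v in ds.variants],
        columns=[str(p) for p in ds.seqpos],
    )
    df.to_csv(path, sep="\t", float_format="%.6f")
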