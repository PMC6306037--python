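"""Readers and writers for the pipeline's external formats.

Formats: presence/absence CSV (Roary ``gene_presence_absence.csv``
dialect or plain 0/1 binary), square identity matrices (CSV or square
PHYLIP), Newick trees, FASTA, predation matrices (CSV), COG annotation
and BGC count tables (TSV), and the aggregated JSON run report.  All
matrices are label-keyed; input label order is preserved.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path
from typing import Dict, List, Union

import numpy as np
import pandas as pd
from Bio import SeqIO
from skbio import TreeNode

from .delimit import IdentityMatrix
from .pam import PresenceAbsenceMatrix

PathLike = Union[str, Path]

#: Fixed metadata columns of Roary's gene_presence_absence.csv; matched
#: by header name (not position) to tolerate dialect drift across
#: Roary versions.
ROARY_METADATA_COLUMNS = {
    "Gene",
    "Non-unique Gene name",
    "Annotation",
    "No. isolates",
    "No. sequences",
    "Avg sequences per isolate",
    "Genome Fragment",
    "Order within Fragment",
    "Accessory Fragment",
    "Accessory Order with Fragment",
    "QC",
    "Min group size nuc",
    "Max group size nuc",
    "Avg group size nuc",
}

# --------------------------------------------------------------------------
# presence/absence
# --------------------------------------------------------------------------

def read_presence_absence(path: PathLike, dialect: str = "binary") -> PresenceAbsenceMatrix:
    """Read a presence/absence matrix.

    ``dialect="binary"``: header row of genome names, one 0/1 row per
    orthogroup.  ``dialect="roary"``: Roary's CSV with its fixed
    metadata columns (recognized by name) followed by one column per
    genome; a cell is "present" iff non-empty.
    """
    path = Path(path)
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh))
    if not rows:
        raise ValueError(f"{path}: empty file")
    header = rows[0]

    if dialect == "binary":
        genomes = header[1:]
        meta_idx: List[int] = []
    elif dialect == "roary":
        meta_idx = [i for i, h in enumerate(header) if h in ROARY_METADATA_COLUMNS]
        if not meta_idx:
            raise ValueError(f"{path}: no Roary metadata columns found in header")
        genomes = [h for i, h in enumerate(header) if i not in meta_idx]
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    if len(set(genomes)) != len(genomes):
        dup = sorted({g for g in genomes if genomes.count(g) > 1})
        raise ValueError(f"{path}: duplicate genome names: {dup}")

    ids: List[str] = []
    data: List[List[bool]] = []
    width = len(header)
    for lineno, row in enumerate(rows[1:], start=2):
        if not row:
            continue
        if len(row) != width:
            raise ValueError(f"{path}:{lineno}: expected {width} fields, found {len(row)}")
        if dialect == "binary":
            ids.append(row[0])
            try:
                data.append([bool(int(c)) for c in row[1:]])
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-0/1 cell in binary matrix") from None
        else:
            ids.append(row[header.index("Gene")] if "Gene" in header else row[0])
            data.append([bool(row[i].strip()) for i in range(width) if i not in meta_idx])
    frame = pd.DataFrame(data, index=ids, columns=genomes)
    return PresenceAbsenceMatrix(frame)


def write_presence_absence(matrix: PresenceAbsenceMatrix, path: PathLike) -> None:
    """Write the binary (0/1 CSV) dialect; round-trips bit-identically."""
    frame = matrix.df.astype(int)
    frame.index.name = "orthogroup"
    frame.to_csv(path)


# --------------------------------------------------------------------------
# identity matrices
# --------------------------------------------------------------------------

_ASYMMETRY_TOLERANCE = 0.5  # percentage points


def _symmetrize(frame: pd.DataFrame, source: str) -> pd.DataFrame:
    v = frame.to_numpy(dtype=float)
    if (v < 0).any() or (v > 100).any():
        bad = v[(v < 0) | (v > 100)][0]
        raise ValueError(f"{source}: identity value {bad} outside [0, 100]")
    gap = np.abs(v - v.T)
    if (gap > _ASYMMETRY_TOLERANCE + 1e-12).any():
        i, j = np.unravel_index(np.argmax(gap), gap.shape)
        raise ValueError(
            f"{source}: asymmetry {v[i, j]} vs {v[j, i]} between "
            f"{frame.index[i]!r} and {frame.index[j]!r} exceeds {_ASYMMETRY_TOLERANCE}"
        )
    sym = (v + v.T) / 2.0
    np.fill_diagonal(sym, 100.0)
    return pd.DataFrame(sym, index=frame.index, columns=frame.columns)


def read_identity_matrix(path: PathLike, fmt: str = "csv", kind: str = "ANI") -> IdentityMatrix:
    """Read a square percentage matrix (ANI or dDDH).

    Asymmetries up to 0.5 percentage points are averaged; larger ones
    are rejected.  The diagonal is forced to 100.
    """
    path = Path(path)
    if fmt == "csv":
        frame = pd.read_csv(path, index_col=0)
        frame.columns = [str(c) for c in frame.columns]
        frame.index = [str(i) for i in frame.index]
    elif fmt == "phylip_square":
        with open(path) as fh:
            tokens = fh.readline().split()
            if not tokens:
                raise ValueError(f"{path}: empty PHYLIP file")
            n = int(tokens[0])
            labels, rows = [], []
            for line in fh:
                parts = line.split()
                if not parts:
                    continue
                labels.append(parts[0])
                rows.append([float(x) for x in parts[1:]])
        if len(labels) != n or any(len(r) != n for r in rows):
            raise ValueError(f"{path}: not a square {n}x{n} PHYLIP matrix")
        frame = pd.DataFrame(rows, index=labels, columns=labels)
    else:
        raise ValueError(f"unknown format {fmt!r}")
    if frame.shape[0] != frame.shape[1]:
        raise ValueError(f"{path}: matrix is {frame.shape[0]}x{frame.shape[1]}, not square")
    if list(frame.index) != list(frame.columns):
        frame.columns = frame.index  # tolerate writers that mangle header labels
    return IdentityMatrix(_symmetrize(frame, str(path)), kind=kind)


def write_identity_matrix(matrix: IdentityMatrix, path: PathLike, fmt: str = "csv") -> None:
    if fmt == "csv":
        matrix.df.to_csv(path)
    elif fmt == "phylip_square":
        with open(path, "w") as fh:
            fh.write(f"{len(matrix.labels)}\n")
            for lab in matrix.labels:
                vals = " ".join(f"{x:.6f}" for x in matrix.df.loc[lab])
                fh.write(f"{lab} {vals}\n")
    else:
        raise ValueError(f"unknown format {fmt!r}")


# --------------------------------------------------------------------------
# trees
# --------------------------------------------------------------------------

def read_newick(path_or_str: Union[PathLike, str]) -> TreeNode:
    """Parse a Newick tree from a path or a literal Newick string."""
    s = str(path_or_str)
    literal = s.strip().endswith(";")
    try:
        return TreeNode.read([s] if literal else s, format="newick")
    except Exception as exc:
        if exc.__class__.__name__ in ("NewickFormatError", "UnrecognizedFormatError"):
            raise ValueError(f"malformed Newick: {exc}") from exc
        raise


def write_newick(tree: TreeNode, path: PathLike) -> None:
    tree.write(str(path), format="newick")


# --------------------------------------------------------------------------
# tables
# --------------------------------------------------------------------------

def read_predation_matrix(path: PathLike) -> pd.DataFrame:
    frame = pd.read_csv(path, index_col=0)
    if frame.isna().any().any():
        raise ValueError(f"{path}: predation matrix has missing cells")
    if (frame.to_numpy() < 0).any():
        raise ValueError(f"{path}: negative killing-zone diameter")
    return frame


def write_predation_matrix(frame: pd.DataFrame, path: PathLike) -> None:
    frame.to_csv(path)


def read_annotations(path: PathLike) -> Dict[str, str]:
    """TSV of gene id -> COG letters (empty second field = unannotated)."""
    table: Dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 1:
                continue
            gene = parts[0]
            letters = parts[1] if len(parts) > 1 else ""
            if gene in table:
                raise ValueError(f"{path}:{lineno}: duplicate gene id {gene!r}")
            table[gene] = letters
    return table


def write_annotations(table: Dict[str, str], path: PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("gene\tcog_letters\n")
        for gene, letters in table.items():
            fh.write(f"{gene}\t{letters}\n")


def read_annotations_table(path: PathLike) -> Dict[str, str]:
    """Annotation TSV with a header row (gene<TAB>cog_letters)."""
    table = read_annotations(path)
    table.pop("gene", None)
    return table


def read_bgc_counts(path: PathLike) -> pd.Series:
    """TSV of genome -> BGC count."""
    frame = pd.read_csv(path, sep="\t", index_col=0)
    series = frame.iloc[:, 0].astype(int)
    if (series < 0).any():
        raise ValueError(f"{path}: negative BGC count")
    return series


def write_bgc_counts(counts: pd.Series, path: PathLike) -> None:
    counts.rename("bgc_count").to_frame().to_csv(path, sep="\t", index_label="genome")


def read_fasta(path: PathLike) -> list:
    return list(SeqIO.parse(str(path), "fasta"))


def write_fasta(records, path: PathLike) -> None:
    SeqIO.write(records, str(path), "fasta")


def read_alignment(path: PathLike) -> Dict[str, str]:
    records = read_fasta(path)
    lengths = {len(r.seq) for r in records}
    if len(lengths) > 1:
        raise ValueError(f"{path}: sequences are not aligned (unequal lengths {sorted(lengths)})")
    return {r.id: str(r.seq) for r in records}


def read_config(path: PathLike) -> "AnalysisConfig":
    """Key=value config file -> AnalysisConfig (unknown keys rejected).

    Tuple-valued fields take comma-separated values, e.g.
    ``partition_thresholds = 0.99, 0.95, 0.15``.
    """
    from .config import AnalysisConfig

    fields = AnalysisConfig.__dataclass_fields__
    kwargs = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected key = value")
            key, _, raw = line.partition("=")
            key = key.strip()
            if key not in fields:
                raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
            parts = [p.strip() for p in raw.split(",")]
            if key in ("rarefaction_permutations", "rng_seed"):
                kwargs[key] = int(parts[0])
            elif len(parts) == 1:
                kwargs[key] = float(parts[0])
            else:
                kwargs[key] = tuple(float(p) for p in parts)
    return AnalysisConfig(**kwargs)


def write_config(config, path: PathLike) -> None:
    with open(path, "w") as fh:
        for key, value in config.to_dict().items():
            if isinstance(value, (tuple, list)):
                fh.write(f"{key} = {', '.join(str(v) for v in value)}\n")
            else:
                fh.write(f"{key} = {value}\n")


def write_json(obj, path: PathLike) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=_default)
        fh.write("\n")
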