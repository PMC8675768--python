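"""Text-format readers and writers.

Dense matrices travel as tab-separated text with ``#``-prefixed header
lines carrying the genomic region (chromosome, start, bin size); sparse
input is accepted as COO triplets (``i  j  value``) or Matrix Market.
Site-of-interest annotations are read from BED (0-based half-open) with the
class label in the name column.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.io import mmread, mmwrite
from scipy.sparse import coo_matrix

__all__ = [
    "RegionHeader",
    "read_contact_matrix",
    "write_dense_matrix",
    "read_dense_matrix",
    "read_soi_bed",
    "write_stiffness",
    "read_stiffness",
]

#: BED label priority when intervals overlap on one bin
_LABEL_PRIORITY = {"S": 3, "P": 2, "E": 1, "#": 0}


@dataclass(frozen=True)
class RegionHeader:
    """Genomic region metadata carried through every file the pipeline writes."""

    chrom: str = "chrU"
    start: int = 0
    bin_size: int = 1
    n_bins: int = 0

    @property
    def end(self) -> int:
        return self.start + self.n_bins * self.bin_size

    def bin_of(self, coord: int) -> int:
        return (coord - self.start) // self.bin_size


def _header_lines(header: RegionHeader, extra: dict | None = None) -> str:
    lines = [
        f"# chrom={header.chrom}",
        f"# start={header.start}",
        f"# bin_size={header.bin_size}",
        f"# n_bins={header.n_bins}",
    ]
    for k, v in (extra or {}).items():
        lines.append(f"# {k}={v}")
    return "\n".join(lines) + "\n"


def _parse_header(path: Path) -> tuple[dict, int]:
    """Parse '# key=value' comment lines; returns (fields, n_comment_lines)."""
    fields: dict[str, str] = {}
    n = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            n += 1
            body = line[1:].strip()
            if "=" in body:
                k, v = body.split("=", 1)
                fields[k.strip()] = v.strip()
    return fields, n


def _region_from_fields(fields: dict, n_bins: int) -> RegionHeader:
    return RegionHeader(
        chrom=fields.get("chrom", "chrU"),
        start=int(fields.get("start", 0)),
        bin_size=int(fields.get("bin_size", 1)),
        n_bins=int(fields.get("n_bins", n_bins)),
    )


def write_dense_matrix(
    path, matrix: np.ndarray, header: RegionHeader, extra: dict | None = None
) -> None:
    """Dense TSV with '#'-header; NaN marks masked cells."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_header_lines(header, extra))
        np.savetxt(fh, np.asarray(matrix), delimiter="\t", fmt="%.10g")


def read_dense_matrix(path) -> tuple[np.ndarray, RegionHeader]:
    path = Path(path)
    fields, skip = _parse_header(path)
    mat = np.loadtxt(path, delimiter="\t", skiprows=skip, ndmin=2)
    return mat, _region_from_fields(fields, mat.shape[0])


def read_contact_matrix(path, format: str = "dense") -> tuple[np.ndarray, RegionHeader]:
    """Read raw contact counts as a symmetric dense matrix.

    ``format`` is one of 'dense', 'coo' (whitespace triplets ``i j value``,
    upper-triangle input mirrored) or 'mtx' (Matrix Market).  Asymmetric
    dense input (beyond 1e-6 relative) and negative counts are format errors.
    """
    path = Path(path)
    if format == "dense":
        mat, header = read_dense_matrix(path)
        if mat.shape[0] != mat.shape[1]:
            raise ValueError("dense contact matrix must be square")
        scale = max(1.0, np.nanmax(np.abs(mat)))
        if not np.allclose(
            np.nan_to_num(mat), np.nan_to_num(mat.T), rtol=1e-6, atol=1e-6 * scale
        ):
            raise ValueError("dense contact matrix is not symmetric")
        mat = np.nan_to_num(0.5 * (mat + mat.T))
    elif format == "coo":
        fields, skip = _parse_header(path)
        trip = np.loadtxt(path, skiprows=skip, ndmin=2)
        if trip.shape[1] != 3:
            raise ValueError("COO input must have three columns: i, j, value")
        i = trip[:, 0].astype(int)
        j = trip[:, 1].astype(int)
        v = trip[:, 2]
        n = int(fields.get("n_bins", max(i.max(), j.max()) + 1))
        mat = np.asarray(
            coo_matrix((v, (i, j)), shape=(n, n)).todense(), dtype=float
        )
        lower = np.tril(mat, -1)
        upper = np.triu(mat, 1)
        # mirror whichever triangle was provided; conflicting duplicates add
        mat = upper + upper.T + lower + lower.T + np.diag(np.diag(mat))
        header = _region_from_fields(fields, n)
    elif format == "mtx":
        sp = mmread(str(path))
        mat = np.asarray(sp.todense(), dtype=float) if hasattr(sp, "todense") else np.asarray(sp)
        if not np.allclose(mat, mat.T, rtol=1e-6, atol=1e-9):
            lower = np.tril(mat, -1)
            upper = np.triu(mat, 1)
            mat = upper + upper.T + lower + lower.T + np.diag(np.diag(mat))
        header = RegionHeader(n_bins=mat.shape[0])
    else:
        raise ValueError(f"unknown format {format!r}")
    if np.any(mat < 0):
        raise ValueError("contact counts must be non-negative")
    return mat, header


def write_mtx(path, matrix: np.ndarray) -> None:
    mmwrite(str(path), coo_matrix(np.asarray(matrix)))


def write_stiffness(path, stiffness, header: RegionHeader | None = None) -> None:
    """Stiffness matrix as dense TSV with the standard header."""
    header = header or RegionHeader(
        start=stiffness.start_coord,
        bin_size=stiffness.bin_size,
        n_bins=stiffness.n_bins,
    )
    write_dense_matrix(path, stiffness.couplings, header, extra={"kind": "stiffness"})


def read_stiffness(path):
    from .polymer import StiffnessMatrix

    mat, header = read_dense_matrix(path)
    mat = 0.5 * (mat + mat.T)
    np.fill_diagonal(mat, 0.0)
    return (
        StiffnessMatrix(
            couplings=mat, bin_size=header.bin_size, start_coord=header.start
        ),
        header,
    )


def read_soi_bed(path, header: RegionHeader) -> np.ndarray:
    """Per-bin site-of-interest labels from a BED file.

    An interval labels every bin it overlaps (0-based half-open); conflicts
    resolve by priority S > P > E > '#'.  Off-region or off-chromosome
    intervals are skipped.
    """
    labels = np.full(header.n_bins, "#", dtype="<U1")
    path = Path(path)
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 4:
                continue
            chrom, start, end, name = parts[0], int(parts[1]), int(parts[2]), parts[3]
            if chrom != header.chrom:
                continue
            if end <= header.start or start >= header.end:
                continue
            lab = name.strip()[:1] or "#"
            if lab not in _LABEL_PRIORITY:
                lab = "#"
            b0 = max(0, (start - header.start) // header.bin_size)
            b1 = min(
                header.n_bins - 1, (end - 1 - header.start) // header.bin_size
            )
            for b in range(b0, b1 + 1):
                if _LABEL_PRIORITY[lab] > _LABEL_PRIORITY[labels[b]]:
                    labels[b] = lab
    return labels


def write_long_format(path, matrix: np.ndarray, header: RegionHeader, viewpoints=()) -> None:
    """Long-format TSV (bin_i, bin_j, viewpoints..., probability)."""
    n = matrix.shape[0]
    vp = ",".join(str(v) for v in viewpoints)
    with open(path, "w") as fh:
        fh.write(_header_lines(header, extra={"viewpoints": vp or "-"}))
        fh.write("bin_i\tbin_j\tviewpoints\tprobability\n")
        for i in range(n):
            for j in range(i + 1, n):
                fh.write(f"{i}\t{j}\t{vp or '-'}\t{matrix[i, j]:.10g}\n")
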