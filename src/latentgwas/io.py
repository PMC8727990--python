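"""Readers and writers for the plain-text formats of the association workflow.

* BEAGLE-style genotype files: whitespace-separated text (optionally gzipped)
  with columns ``marker allele1 allele2`` followed by three genotype columns
  per individual.  Triplets are validated and renormalized on load (input
  tolerance 1e-3 on the row sum, hard failure outside [0.9, 1.1]).
* phenotype/covariate tables: header plus one row per individual, first
  column the phenotype, remaining columns covariates, ``NA`` for missing;
  sample order is positional and must match the genotype file.
* plain numeric matrices for admixture proportions (Q) and population
  frequencies (F).
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "BeagleTable",
    "read_beagle",
    "write_beagle",
    "read_pheno_cov",
    "read_matrix",
    "BeagleParseError",
]


class BeagleParseError(ValueError):
    pass


@dataclass
class BeagleTable:
    """Parsed genotype-probability file: markers and per-marker N x 3 triplets."""

    markers: list[tuple[str, str, str]]
    probs: list[np.ndarray]
    sample_count: int

    @property
    def n_markers(self) -> int:
        return len(self.markers)


def _open(path, mode="rt"):
    if str(path).endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def read_beagle(path) -> BeagleTable:
    """Parse a BEAGLE genotype-probability file, renormalizing each triplet."""
    markers: list[tuple[str, str, str]] = []
    rows: list[np.ndarray] = []
    n_samples = None
    with _open(path) as fh:
        header = fh.readline()
        if not header.strip():
            raise BeagleParseError(f"{path}: empty file")
        ncol_header = len(header.split())
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.split()
            if n_samples is None:
                if (len(parts) - 3) % 3 != 0 or len(parts) <= 3:
                    raise BeagleParseError(
                        f"{path}:{lineno}: expected 3 + 3*N columns, got {len(parts)}"
                    )
                n_samples = (len(parts) - 3) // 3
            if len(parts) != 3 + 3 * n_samples:
                raise BeagleParseError(
                    f"{path}:{lineno}: ragged row ({len(parts)} columns, "
                    f"expected {3 + 3 * n_samples})"
                )
            try:
                vals = np.array(parts[3:], dtype=float)
            except ValueError as err:
                raise BeagleParseError(f"{path}:{lineno}: non-numeric probability "
                                       f"({err})") from None
            trip = vals.reshape(n_samples, 3)
            sums = trip.sum(axis=1)
            if np.any((sums < 0.9) | (sums > 1.1)) or np.any(trip < 0):
                bad = int(np.argmax((sums < 0.9) | (sums > 1.1)))
                raise BeagleParseError(
                    f"{path}:{lineno}: genotype triplet for individual {bad} "
                    f"sums to {sums[bad]:.4f} (must be within [0.9, 1.1])"
                )
            markers.append((parts[0], parts[1], parts[2]))
            rows.append(trip / sums[:, None])
    if not rows:
        raise BeagleParseError(f"{path}: no marker rows")
    _ = ncol_header  # header column count is not enforced (dialects vary)
    return BeagleTable(markers=markers, probs=rows, sample_count=n_samples)


def write_beagle(table: BeagleTable, path) -> None:
    """Write a BeagleTable as whitespace-separated genotype-probability text."""
    with _open(path, "wt") as fh:
        cols = ["marker", "allele1", "allele2"]
        for i in range(table.sample_count):
            cols.extend([f"Ind{i}"] * 3)
        fh.write("\t".join(cols) + "\n")
        for (mid, a1, a2), trip in zip(table.markers, table.probs):
            body = "\t".join(f"{v:.6f}" for v in np.asarray(trip).ravel())
            fh.write(f"{mid}\t{a1}\t{a2}\t{body}\n")


def read_pheno_cov(path, n_expected: int | None = None):
    """Read a phenotype/covariate table.

    Returns ``(y, Z, complete_mask, binary)`` where Z is None when there are
    no covariate columns, ``complete_mask`` marks rows with no missing values
    and ``binary`` says whether the phenotype column is {0, 1}.
    """
    df = pd.read_csv(path, sep=r"\s+", na_values=["NA"])
    for col in df.columns:
        if not np.issubdtype(df[col].dtype, np.number):
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()
                          & df[col].notna()]
            raise ValueError(
                f"{path}: non-numeric value {bad.iloc[0]!r} in column {col!r}"
            )
    if n_expected is not None and len(df) != n_expected:
        raise ValueError(
            f"{path}: {len(df)} rows but genotype file has {n_expected} individuals"
        )
    y = df.iloc[:, 0].to_numpy(dtype=float)
    Z = df.iloc[:, 1:].to_numpy(dtype=float) if df.shape[1] > 1 else None
    mask = ~np.isnan(y)
    if Z is not None:
        mask &= ~np.isnan(Z).any(axis=1)
    finite_y = y[~np.isnan(y)]
    binary = np.all(np.isin(finite_y, [0.0, 1.0])) and finite_y.size > 0
    return y, Z, mask, bool(binary)


def read_matrix(path) -> np.ndarray:
    """Plain whitespace-separated numeric matrix (Q or population frequencies)."""
    arr = np.loadtxt(path, ndmin=2)
    return arr
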