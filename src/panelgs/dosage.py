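"""Genotype matrix container shared by every stage of the pipeline.

A :class:`DosageMatrix` holds a lines x markers genotype matrix together with
its marker map.  Two codings exist:

* *raw* / *imputed*: integer codes ``0`` (homozygous reference), ``1``
  (heterozygous), ``2`` (homozygous alternate) and ``-9`` (missing call).
* *final*: ``+1`` for homozygous reference and ``-1`` for homozygous
  alternate, the coding used by all whole-genome regression models.  The
  orientation (reference allele maps to ``+1``) is a fixed convention;
  flipping it flips the sign of every estimated marker effect but nothing
  else.

The ``coding_state`` attribute enforces the QC pipeline order
raw -> imputed -> final: operations check the state they require and raise
on out-of-order calls.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

HOM_REF = 0
HET = 1
HOM_ALT = 2
MISSING = -9

_CODING_STATES = ("raw", "imputed", "final")


def marker_table(chrom, pos, ref=None, alt=None, ids=None) -> pd.DataFrame:
    """Assemble a marker map DataFrame with columns id, chrom, pos, ref, alt."""
    chrom = np.asarray(chrom)
    pos = np.asarray(pos, dtype=np.int64)
    n = len(pos)
    if ids is None:
        ids = [f"{c}_{p}" for c, p in zip(chrom, pos)]
    if ref is None:
        ref = np.full(n, "A")
    if alt is None:
        alt = np.full(n, "T")
    return pd.DataFrame(
        {"id": ids, "chrom": chrom, "pos": pos, "ref": ref, "alt": alt}
    )


@dataclass
class DosageMatrix:
    """Lines x markers genotype matrix with marker map and coding state.

    Parameters
    ----------
    values
        ``(n_lines, n_markers)`` integer array in the coding implied by
        ``coding_state``.
    markers
        DataFrame with columns ``id, chrom, pos, ref, alt``; positions are
        1-based and strictly increasing within each chromosome.
    lines
        Unique line identifiers, one per row.
    coding_state
        One of ``raw``, ``imputed``, ``final``.
    """

    values: np.ndarray
    markers: pd.DataFrame
    lines: list = field(default_factory=list)
    coding_state: str = "raw"

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D lines x markers array")
        if self.values.size == 0:
            raise ValueError("empty genotype matrix")
        n_lines, n_markers = self.values.shape
        if len(self.lines) != n_lines:
            raise ValueError("number of line ids does not match rows")
        if len(self.markers) != n_markers:
            raise ValueError("marker map length does not match columns")
        if self.coding_state not in _CODING_STATES:
            raise ValueError(f"unknown coding_state {self.coding_state!r}")
        if len(set(self.lines)) != n_lines:
            raise ValueError("line ids are not unique")
        if self.markers["id"].duplicated().any():
            raise ValueError("marker ids are not unique")
        for _, grp in self.markers.groupby("chrom", sort=False):
            p = grp["pos"].to_numpy()
            if np.any(np.diff(p) <= 0):
                raise ValueError(
                    "marker positions must be strictly increasing within chromosome"
                )
        allowed = (
            {HOM_REF, HET, HOM_ALT, MISSING}
            if self.coding_state == "raw"
            else {HOM_REF, HET, HOM_ALT}
            if self.coding_state == "imputed"
            else {-1, 1}
        )
        present = set(np.unique(self.values).tolist())
        if not present <= allowed:
            raise ValueError(
                f"values {sorted(present - allowed)} invalid for "
                f"coding_state={self.coding_state!r}"
            )

    # -- shape ------------------------------------------------------------
    @property
    def n_lines(self) -> int:
        return self.values.shape[0]

    @property
    def n_markers(self) -> int:
        return self.values.shape[1]

    # -- subsetting -------------------------------------------------------
    def take_markers(self, index) -> "DosageMatrix":
        """Return a copy restricted to the marker columns in ``index``."""
        index = np.asarray(index)
        return replace(
            self,
            values=self.values[:, index].copy(),
            markers=self.markers.iloc[index].reset_index(drop=True),
        )

    def take_lines(self, index) -> "DosageMatrix":
        """Return a copy restricted to the line rows in ``index``."""
        index = np.asarray(index)
        return replace(
            self,
            values=self.values[index].copy(),
            markers=self.markers.copy(),
            lines=[self.lines[i] for i in index],
        )

    def require_state(self, *states: str) -> None:
        if self.coding_state not in states:
            raise ValueError(
                f"operation requires coding_state in {states}, "
                f"got {self.coding_state!r}"
            )

    def copy(self) -> "DosageMatrix":
        return replace(
            self,
            values=self.values.copy(),
            markers=self.markers.copy(),
            lines=list(self.lines),
        )
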