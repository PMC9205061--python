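"""Residue-residue contact probability maps.

A contact map for a protein of N residues is an N x N symmetric matrix of
contact probabilities in [0, 1].  Maps are produced upstream by a contact
predictor (e.g. a protein language model); this module loads them from disk,
synthesizes realistic stand-ins, and implements the sliding-window
split/merge scheme used when a predictor cannot accept sequences longer
than its input limit (here L = 1000 residues): the sequence is cut into
windows of length L with step L/2, each window is predicted independently,
and overlapping entries of the reassembled map are averaged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "ContactMap",
    "WindowPlan",
    "ContactMapFormatError",
    "load_contact_map",
    "save_contact_map",
    "synth_contact_map",
    "plan_windows",
    "split_contact_map",
    "merge_contact_maps",
]

DEFAULT_WINDOW_LENGTH = 1000
DEFAULT_WINDOW_STEP = 500


class ContactMapFormatError(ValueError):
    """Raised when an on-disk contact map is malformed (e.g. non-square)."""


@dataclass(frozen=True)
class ContactMap:
    """Symmetric matrix of residue-residue contact probabilities.

    Parameters
    ----------
    probs
        Square ``(length, length)`` array with entries in ``[0, 1]``.
        Symmetry is enforced at construction by averaging with the
        transpose (predictor outputs are often only approximately
        symmetric).
    """

    probs: np.ndarray

    def __post_init__(self) -> None:
        probs = np.asarray(self.probs, dtype=np.float64)
        if probs.ndim != 2 or probs.shape[0] != probs.shape[1]:
            raise ContactMapFormatError(
                f"contact map must be square, got shape {probs.shape}"
            )
        probs = (probs + probs.T) / 2.0
        if probs.min() < -1e-6 or probs.max() > 1 + 1e-6:
            warnings.warn(
                "contact probabilities outside [0, 1] by more than 1e-6; "
                "clipping",
                stacklevel=2,
            )
        probs = np.clip(probs, 0.0, 1.0)
        probs.flags.writeable = False
        object.__setattr__(self, "probs", probs)

    @property
    def length(self) -> int:
        """Number of residues."""
        return self.probs.shape[0]

    def __eq__(self, other: object) -> bool:  # array-valued field
        if not isinstance(other, ContactMap):
            return NotImplemented
        return np.array_equal(self.probs, other.probs)

    __hash__ = None  # type: ignore[assignment]


@dataclass(frozen=True)
class WindowPlan:
    """Ordered half-open windows covering ``[0, total_length)``.

    Consecutive windows overlap by ``window_length - step`` residues,
    except possibly the last, whose end is clamped to the sequence end.
    """

    windows: tuple[tuple[int, int], ...]
    window_length: int = DEFAULT_WINDOW_LENGTH
    step: int = DEFAULT_WINDOW_STEP

    @property
    def total_length(self) -> int:
        return self.windows[-1][1]


def load_contact_map(path: str | Path, dialect: str = "matrix-text") -> ContactMap:
    """Read a contact map from disk.

    ``matrix-text`` is the canonical dialect: a whitespace-delimited square
    matrix, one row per line.  ``binary`` reads a NumPy ``.npy`` array.
    Asymmetric inputs are symmetrized by averaging with the transpose;
    values outside [0, 1] by more than 1e-6 trigger a warning and are
    clipped.

    Raises
    ------
    ContactMapFormatError
        If the matrix is not square (the row and column counts are named
        in the message) or rows are ragged.
    OSError
        If the file cannot be read.
    """
    path = Path(path)
    if dialect == "matrix-text":
        rows: list[list[float]] = []
        with open(path) as fh:
            for line in fh:
                if line.strip():
                    rows.append([float(tok) for tok in line.split()])
        if not rows:
            raise ContactMapFormatError(f"{path}: empty contact map file")
        ncols = {len(r) for r in rows}
        if len(ncols) > 1:
            raise ContactMapFormatError(
                f"{path}: ragged rows with column counts {sorted(ncols)}"
            )
        mat = np.asarray(rows, dtype=np.float64)
    elif dialect == "binary":
        mat = np.load(path)
    else:
        raise ValueError(f"unknown contact-map dialect {dialect!r}")
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise ContactMapFormatError(
            f"{path}: non-square matrix with {mat.shape[0]} rows and "
            f"{mat.shape[1] if mat.ndim == 2 else '?'} columns"
        )
    return ContactMap(mat)


def save_contact_map(
    cmap: ContactMap, path: str | Path, dialect: str = "matrix-text"
) -> None:
    """Write a contact map in the given dialect (inverse of load)."""
    path = Path(path)
    if dialect == "matrix-text":
        np.savetxt(path, cmap.probs, fmt="%.8g")
    elif dialect == "binary":
        np.save(path, cmap.probs)
    else:
        raise ValueError(f"unknown contact-map dialect {dialect!r}")


def synth_contact_map(
    length: int,
    seed: int,
    band_width: int = 4,
    long_range_density: float = 0.02,
) -> ContactMap:
    """Synthesize a contact map with realistic structure.

    Emulates the qualitative shape of predicted maps: probability 1 on the
    diagonal, strong near-diagonal contacts (``|i - j| <= band_width``
    drawn uniformly in [0.6, 1]), a sparse ``long_range_density`` fraction
    of the remaining pairs drawn in (0.5, 1] (supra-threshold long-range
    contacts), and everything else sub-threshold in [0, 0.5).  Output is
    deterministic per seed and exactly symmetric.
    """
    if length < 2:
        raise ValueError(f"contact map length must be >= 2, got {length}")
    if not 0.0 <= long_range_density <= 1.0:
        raise ValueError(
            f"long_range_density must be in [0, 1], got {long_range_density}"
        )
    rng = np.random.default_rng(seed)
    probs = np.zeros((length, length))
    iu, ju = np.triu_indices(length, k=1)
    off = np.abs(iu - ju)
    in_band = off <= band_width
    vals = np.empty(iu.size)
    vals[in_band] = rng.uniform(0.6, 1.0, in_band.sum())
    n_far = int((~in_band).sum())
    contact = np.zeros(n_far, dtype=bool)
    n_contact = int(round(long_range_density * n_far))
    if n_contact:
        contact[rng.choice(n_far, size=n_contact, replace=False)] = True
    far_vals = rng.uniform(0.0, 0.5, n_far)
    # supra-threshold long-range contacts: flip into (0.5, 1]
    far_vals[contact] = 1.0 - far_vals[contact]
    vals[~in_band] = far_vals
    probs[iu, ju] = vals
    probs[ju, iu] = vals
    np.fill_diagonal(probs, 1.0)
    return ContactMap(probs)


def plan_windows(
    sequence_length: int,
    window_length: int = DEFAULT_WINDOW_LENGTH,
    step: int = DEFAULT_WINDOW_STEP,
) -> WindowPlan:
    """Plan sliding windows of length ``window_length`` and the given step.

    A sequence no longer than ``window_length`` gets a single window
    ``(0, sequence_length)``.  Longer sequences get windows starting at
    0, step, 2*step, ...; the final window's end is clamped to the
    sequence end rather than padded, so no residues are fabricated.
    """
    if sequence_length < 1:
        raise ValueError(f"sequence_length must be >= 1, got {sequence_length}")
    if step <= 0 or step > window_length:
        raise ValueError(
            f"step must satisfy 0 < step <= window_length "
            f"({step} vs {window_length}): larger steps leave coverage gaps"
        )
    if sequence_length <= window_length:
        return WindowPlan(((0, sequence_length),), window_length, step)
    windows: list[tuple[int, int]] = []
    start = 0
    while start + window_length < sequence_length:
        windows.append((start, start + window_length))
        start += step
    windows.append((start, sequence_length))
    return WindowPlan(tuple(windows), window_length, step)


def split_contact_map(cmap: ContactMap, plan: WindowPlan) -> list[ContactMap]:
    """Slice a full map into per-window diagonal blocks (the maps a
    windowed predictor would emit)."""
    return [ContactMap(cmap.probs[s:e, s:e]) for s, e in plan.windows]


def merge_contact_maps(
    submaps: Sequence[ContactMap],
    plan: WindowPlan,
    total_length: int,
) -> ContactMap:
    """Reassemble a full-length map from per-window maps.

    Entry ``(i, j)`` is the mean of the submap values over every window
    containing both residues; pairs never co-resident in any window (their
    separation exceeds the overlap reach) get probability 0, i.e. no
    predicted contact.  With a single full-length window the input map is
    returned bit-identically.
    """
    if len(submaps) != len(plan.windows):
        raise ValueError(
            f"{len(submaps)} submaps for {len(plan.windows)} windows"
        )
    if plan.windows[-1][1] != total_length:
        raise ValueError(
            f"plan covers {plan.windows[-1][1]} residues, expected {total_length}"
        )
    if len(submaps) == 1 and plan.windows[0] == (0, total_length):
        return submaps[0]
    acc = np.zeros((total_length, total_length))
    cnt = np.zeros((total_length, total_length))
    for sub, (s, e) in zip(submaps, plan.windows):
        if sub.length != e - s:
            raise ValueError(
                f"submap of side {sub.length} does not match window "
                f"({s}, {e}) of length {e - s}"
            )
        acc[s:e, s:e] += sub.probs
        cnt[s:e, s:e] += 1.0
    covered = cnt > 0
    acc[covered] /= cnt[covered]
    return ContactMap(acc)
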