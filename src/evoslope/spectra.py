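"""Log-spectral slopes: global, per-class and sliding-window ("evolutionary").

The slope of a transformed matrix Z is

    s = log(mean Z2**2) - log(mean Z1**2)

where Z2 collects the finest detail coefficients of the 2-D scale-mixing
transform and Z1 the next coarser level.  A negative slope means the
finest level carries *less* energy than the coarser one — the signature
of regularity (persistence); s = 0 matches independent random letters;
positive slopes indicate anti-persistent zig-zagging.  For a pure
monofractal of Hurst exponent H in dimension d the slope calibrates to
-(2H + d); a maximally smooth homopolymer window (H = 1, d = 1) therefore
gives exactly -log 8.

Block layouts (1-based, width N):

* 4-row (single-code) Z:   Z1 = Z(2,    N/4+1 : N/2),  Z2 = Z(3:4,  N/2+1 : N)
* 16-row (invariant)  Z:   Z1 = Z(5:7,  N/4+1 : N/2),  Z2 = Z(9:14, N/2+1 : N)

Rows 8, 15 and 16 of the 16-row transform are details of the zero padding
rows and are excluded.  Both column ranges lie in detail blocks of the
column transform, so adding a per-row constant to Y* changes nothing —
which is why slicing a global cumulative matrix and restarting the
cumulative sums inside each window give identical window slopes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterator

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .encoding import (
    DEFAULT_REPRESENTATIVES,
    NucleotideSequence,
    as_sequence,
    cumulate,
    encode_invariant,
    encode_single,
    invalid_mask,
)
from .wavelet import (
    DEFAULT_MALLAT_THRESHOLD,
    ShapeError,
    build_haar_matrix,
    dwt_rows,
    scale_mixing_transform,
)


class SequenceTooShortError(ValueError):
    """Sequence shorter than the minimum the slope is defined on."""


class ParameterError(ValueError):
    """Invalid window/step parameters."""


@dataclass(frozen=True)
class LevelLayout:
    """1-based inclusive index ranges of the Z1/Z2 detail blocks."""

    z1_rows: tuple[int, int]
    z1_cols: tuple[int, int]
    z2_rows: tuple[int, int]
    z2_cols: tuple[int, int]

    def z1(self, Z: np.ndarray) -> np.ndarray:
        (r0, r1), (c0, c1) = self.z1_rows, self.z1_cols
        return Z[r0 - 1 : r1, c0 - 1 : c1]

    def z2(self, Z: np.ndarray) -> np.ndarray:
        (r0, r1), (c0, c1) = self.z2_rows, self.z2_cols
        return Z[r0 - 1 : r1, c0 - 1 : c1]


def detail_layout(n_rows: int, n_cols: int) -> LevelLayout:
    """Standard Z1/Z2 layout for a 4-row or 16-row transform of width N."""
    if n_cols % 4:
        raise ShapeError(f"width {n_cols} not divisible by 4")
    q, h = n_cols // 4, n_cols // 2
    if n_rows == 4:
        return LevelLayout((2, 2), (q + 1, h), (3, 4), (h + 1, n_cols))
    if n_rows == 16:
        return LevelLayout((5, 7), (q + 1, h), (9, 14), (h + 1, n_cols))
    raise ShapeError(f"no standard layout for {n_rows}-row transforms")


@dataclass(frozen=True)
class SpectralSlope:
    """A slope with its two mean energies.

    ``s`` may be +-inf (one energy zero) or NaN (missing: both energies
    zero, or the window contained unmappable residues).
    """

    s: float
    e1: float
    e2: float
    log_base: str = "e"
    used_length: int | None = None

    @property
    def flag(self) -> str:
        if math.isnan(self.s):
            return "missing"
        if math.isinf(self.s):
            return "pos_inf" if self.s > 0 else "neg_inf"
        return "finite"

    @property
    def is_finite(self) -> bool:
        return math.isfinite(self.s)


def _log(x: float, base: str) -> float:
    return math.log2(x) if base == "2" else math.log(x)


def slope_from_energies(
    e1: float, e2: float, log_base: str = "e", used_length: int | None = None
) -> SpectralSlope:
    """Map the (e1, e2) energy pair to a slope, handling degenerate zeros."""
    if e1 > 0 and e2 > 0:
        s = _log(e2, log_base) - _log(e1, log_base)
    elif e1 > 0:
        s = -math.inf
    elif e2 > 0:
        s = math.inf
    else:
        s = math.nan
    return SpectralSlope(s, e1, e2, log_base, used_length)


def missing_slope(log_base: str = "e", used_length: int | None = None) -> SpectralSlope:
    return SpectralSlope(math.nan, math.nan, math.nan, log_base, used_length)


def spectral_slope(
    Z: np.ndarray, layout: LevelLayout | None = None, log_base: str = "e"
) -> SpectralSlope:
    """Slope of an already-transformed matrix Z."""
    Z = np.asarray(Z, dtype=float)
    if layout is None:
        layout = detail_layout(*Z.shape)
    e1 = float(np.mean(layout.z1(Z) ** 2))
    e2 = float(np.mean(layout.z2(Z) ** 2))
    return slope_from_energies(e1, e2, log_base)


def _encode(
    residues: str,
    mode: str,
    code: str,
    representatives: tuple[str, str, str],
    strict: bool,
) -> np.ndarray:
    if mode == "invariant":
        return encode_invariant(residues, representatives, strict=strict)
    if mode == "single":
        return encode_single(residues, code, strict=strict)
    raise ParameterError(f"unknown mode {mode!r} (expected 'invariant' or 'single')")


def global_slope(
    seq: NucleotideSequence | str,
    mode: str = "invariant",
    code: str = "ACGT",
    representatives: tuple[str, str, str] = DEFAULT_REPRESENTATIVES,
    log_base: str = "e",
    strict: bool = False,
    mallat_threshold: int = DEFAULT_MALLAT_THRESHOLD,
) -> SpectralSlope:
    """Slope of a whole sequence, truncated to its longest power-of-two prefix.

    The transform needs a dyadic width, so a length-877 input is scored on
    its first 512 residues (the tail is dropped, not the head).  Sequences
    shorter than 8 raise; a prefix containing unmappable residues yields a
    missing slope unless ``strict``.
    """
    s = as_sequence(seq)
    n = len(s)
    if n < 8:
        raise SequenceTooShortError(f"length {n} < 8 for sequence {s.id!r}")
    used = 1 << int(math.floor(math.log2(n)))
    prefix = s.residues[:used]
    if invalid_mask(prefix).any():
        if strict:
            _encode(prefix, mode, code, representatives, strict=True)
        return missing_slope(log_base, used)
    Y = _encode(prefix, mode, code, representatives, strict=strict)
    Z = scale_mixing_transform(cumulate(Y), mallat_threshold=mallat_threshold)
    out = spectral_slope(Z, log_base=log_base)
    return replace(out, used_length=used)


@dataclass(frozen=True)
class ClassSlopes:
    """Per-equivalence-class slopes (s1, s2, s3) and their plain average."""

    slopes: tuple[SpectralSlope, SpectralSlope, SpectralSlope]
    mean: float


def per_class_slopes(
    seq: NucleotideSequence | str,
    log_base: str = "e",
    representatives: tuple[str, str, str] = DEFAULT_REPRESENTATIVES,
    **kwargs,
) -> ClassSlopes:
    """The three single-code slopes, one per equivalence class.

    Well-defined because every member of a class gives the same slope;
    averaging them is the simple (pre-stacking) way to get an
    assignment-independent summary.
    """
    slopes = tuple(
        global_slope(seq, mode="single", code=rep, log_base=log_base, **kwargs)
        for rep in representatives
    )
    values = [sl.s for sl in slopes]
    mean = sum(values) / 3 if all(math.isfinite(v) for v in values) else math.nan
    return ClassSlopes(slopes, mean)  # type: ignore[arg-type]


@dataclass(frozen=True)
class SlopeSeries:
    """Windowed slopes along a sequence (the cumulative evolutionary slope).

    ``starts`` are 1-based window start positions spaced by ``step``; the
    trailing partial window is discarded.  +-inf and missing slopes are
    retained so downstream exclusion stays explicit and countable.
    """

    seq_id: str
    window: int
    step: int
    starts: np.ndarray
    slopes: tuple[SpectralSlope, ...]
    mode: str
    log_base: str

    def __len__(self) -> int:
        return len(self.slopes)

    def __iter__(self) -> Iterator[SpectralSlope]:
        return iter(self.slopes)

    @property
    def values(self) -> np.ndarray:
        """Slope values as a float array (inf/NaN preserved)."""
        return np.array([sl.s for sl in self.slopes])

    @property
    def ends(self) -> np.ndarray:
        return self.starts + self.window - 1

    def to_tsv(self, handle) -> None:
        """Write seq_id / window_start / window_end / slope / e1 / e2 / flag."""
        handle.write("seq_id\twindow_start\twindow_end\tslope\te1\te2\tflag\n")
        for start, end, sl in zip(self.starts, self.ends, self.slopes):
            handle.write(
                f"{self.seq_id}\t{start}\t{end}\t{format_value(sl.s)}\t"
                f"{format_value(sl.e1)}\t{format_value(sl.e2)}\t{sl.flag}\n"
            )


def format_value(x: float) -> str:
    """Serialize a possibly non-finite number ("NA", "+inf", "-inf")."""
    if math.isnan(x):
        return "NA"
    if math.isinf(x):
        return "+inf" if x > 0 else "-inf"
    return f"{x:.10g}"


def evolutionary_slope(
    seq: NucleotideSequence | str,
    window: int = 32,
    step: int = 8,
    mode: str = "invariant",
    code: str = "ACGT",
    representatives: tuple[str, str, str] = DEFAULT_REPRESENTATIVES,
    log_base: str = "e",
    strict: bool = False,
    engine: str = "sliced",
) -> SlopeSeries:
    """Slopes of a width-``window`` window slid along the sequence.

    Window width and step must be divisible by 4 (the Haar depth-2
    alignment requirement).  ``engine='sliced'`` slices the global
    cumulative matrix (fast, vectorised); ``engine='restart'`` re-encodes
    and re-accumulates each window independently.  The two are
    mathematically identical because the detail blocks annihilate the
    per-row constant offset that distinguishes them.
    """
    s = as_sequence(seq)
    n = len(s)
    if window % 4 or window < 8:
        raise ParameterError(f"window {window} must be divisible by 4 and >= 8")
    if step % 4 or step < 4:
        raise ParameterError(f"step {step} must be a positive multiple of 4")
    if n < window:
        raise ParameterError(f"sequence length {n} < window {window}")

    starts0 = np.arange(0, n - window + 1, step)
    bad = invalid_mask(s.residues)
    if strict and bad.any():
        _encode(s.residues, mode, code, representatives, strict=True)
    cum_bad = np.concatenate([[0], np.cumsum(bad)])
    window_bad = cum_bad[starts0 + window] - cum_bad[starts0] > 0

    Y = _encode(s.residues, mode, code, representatives, strict=False)
    layout = detail_layout(Y.shape[0], window)

    if engine == "sliced":
        e1, e2 = _window_energies_sliced(Y, starts0, window, layout)
    elif engine == "restart":
        e1, e2 = _window_energies_restart(Y, starts0, window, layout, log_base)
    else:
        raise ParameterError(f"unknown engine {engine!r}")

    slopes = tuple(
        missing_slope(log_base, window)
        if window_bad[i]
        else slope_from_energies(float(e1[i]), float(e2[i]), log_base, window)
        for i in range(len(starts0))
    )
    return SlopeSeries(
        seq_id=s.id,
        window=window,
        step=step,
        starts=starts0 + 1,
        slopes=slopes,
        mode=mode,
        log_base=log_base,
    )


def _window_energies_sliced(
    Y: np.ndarray, starts0: np.ndarray, window: int, layout: LevelLayout
) -> tuple[np.ndarray, np.ndarray]:
    # Slice the global cumulative matrix: per-window constant row offsets
    # vanish in the detail blocks, so this equals restarting the sums.
    Ystar = cumulate(Y)
    view = sliding_window_view(Ystar, window, axis=1)[:, starts0, :]
    arr = np.ascontiguousarray(np.moveaxis(view, 1, 0))  # (n_win, rows, window)
    Wr = build_haar_matrix(Y.shape[0], 2)
    T = np.einsum("ab,nbk->nak", Wr, arr)
    Z = dwt_rows(T, 2)
    (r0, r1), (c0, c1) = layout.z1_rows, layout.z1_cols
    e1 = np.mean(Z[:, r0 - 1 : r1, c0 - 1 : c1] ** 2, axis=(1, 2))
    (r0, r1), (c0, c1) = layout.z2_rows, layout.z2_cols
    e2 = np.mean(Z[:, r0 - 1 : r1, c0 - 1 : c1] ** 2, axis=(1, 2))
    return e1, e2


def _window_energies_restart(
    Y: np.ndarray,
    starts0: np.ndarray,
    window: int,
    layout: LevelLayout,
    log_base: str,
) -> tuple[np.ndarray, np.ndarray]:
    e1 = np.empty(len(starts0))
    e2 = np.empty(len(starts0))
    for i, s0 in enumerate(starts0):
        Yw = Y[:, s0 : s0 + window]
        Z = scale_mixing_transform(cumulate(Yw))
        e1[i] = np.mean(layout.z1(Z) ** 2)
        e2[i] = np.mean(layout.z2(Z) ** 2)
    return e1, e2
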