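"""Match-style PWM scanning: information vector, core/matrix similarity, scan.

A window's matrix similarity score (MSS) rescales its information-weighted
frequency sum between the worst and best attainable windows:

    MSS = (Current - Min) / (Max - Min)
    Current = sum_i I(i) * f(i, b_i)
    I(i)    = sum_b f(i, b) * ln(4 f(i, b))      (0 * ln 0 := 0)

The core similarity applies the same formula to the 5 consecutive positions
of highest total information (leftmost on ties; the whole matrix when L <= 5).
Candidate binding elements are windows passing both the core and the matrix
cut-off on either strand.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_io import BASE_INDEX, PWM, GenomicInterval, ValidationError

CORE_LENGTH = 5
DEFAULT_CORE_CUTOFF = 0.75
DEFAULT_MATRIX_CUTOFF = 0.85

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class InformationVector:
    values: np.ndarray  # (L,), nats, each in [0, ln 4]


@dataclass(frozen=True)
class TFBEHit:
    """A predicted binding element inside a scanned region."""

    region_id: str
    matrix: str
    chrom: str
    start: int  # forward-strand genome offset of the matched window
    strand: str
    core_score: float
    matrix_score: float
    sequence: str

    @property
    def end(self) -> int:
        return self.start + len(self.sequence)

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos < self.end


def information_vector(pwm: PWM) -> InformationVector:
    f = pwm.freqs
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(f > 0, f * np.log(4.0 * f), 0.0)
    return InformationVector(terms.sum(axis=1))


def core_positions(pwm: PWM) -> tuple[int, int]:
    """[start, end) of the core: the 5-mer of maximal total information.

    Leftmost window wins ties; matrices of length <= 5 are their own core.
    """
    L = len(pwm)
    if L <= CORE_LENGTH:
        return 0, L
    info = information_vector(pwm).values
    sums = np.convolve(info, np.ones(CORE_LENGTH), mode="valid")
    start = int(np.argmax(sums))  # argmax returns the first maximum
    return start, start + CORE_LENGTH


def _encode(window: str) -> np.ndarray | None:
    """Base indices for a window, or None if it contains non-ACGT."""
    try:
        return np.fromiter(
            (BASE_INDEX[b] for b in window.upper()), dtype=np.intp, count=len(window)
        )
    except KeyError:
        return None


def _mss(freqs: np.ndarray, info: np.ndarray, codes: np.ndarray) -> float:
    current = float((info * freqs[np.arange(len(codes)), codes]).sum())
    max_ = float((info * freqs.max(axis=1)).sum())
    min_ = float((info * freqs.min(axis=1)).sum())
    if max_ == min_:
        return 0.0
    return (current - min_) / (max_ - min_)


def matrix_similarity(pwm: PWM, window: str) -> float:
    """MSS of one window against the whole matrix; in [0, 1]."""
    if len(window) != len(pwm):
        raise ValidationError(
            f"window length {len(window)} != matrix length {len(pwm)}"
        )
    codes = _encode(window)
    if codes is None:
        raise ValidationError(f"window contains non-ACGT base: {window!r}")
    return _mss(pwm.freqs, information_vector(pwm).values, codes)


def core_similarity(pwm: PWM, window: str) -> float:
    """MSS restricted to the matrix core; equals MSS when L <= 5."""
    if len(window) != len(pwm):
        raise ValidationError(
            f"window length {len(window)} != matrix length {len(pwm)}"
        )
    codes = _encode(window)
    if codes is None:
        raise ValidationError(f"window contains non-ACGT base: {window!r}")
    s, e = core_positions(pwm)
    info = information_vector(pwm).values
    return _mss(pwm.freqs[s:e], info[s:e], codes[s:e])


def scan_sequence(
    pwm: PWM,
    sequence: str,
    core_cutoff: float = DEFAULT_CORE_CUTOFF,
    matrix_cutoff: float = DEFAULT_MATRIX_CUTOFF,
    region_id: str = "",
    chrom: str = "",
    offset: int = 0,
) -> list[TFBEHit]:
    """Score every window on both strands; report those passing both cut-offs.

    Reverse-strand windows are scored on the reverse complement; reported
    coordinates stay on the forward strand. Windows containing N are skipped.
    Sequences shorter than the matrix yield an empty list.
    """
    for name, c in (("core", core_cutoff), ("matrix", matrix_cutoff)):
        if not 0.0 <= c <= 1.0:
            raise ValidationError(f"{name} cutoff must lie in [0, 1], got {c}")
    L = len(pwm)
    n = len(sequence) - L + 1
    if n <= 0:
        return []
    freqs = pwm.freqs
    info = information_vector(pwm).values
    cs, ce = core_positions(pwm)
    max_full = float((info * freqs.max(axis=1)).sum())
    min_full = float((info * freqs.min(axis=1)).sum())
    max_core = float((info[cs:ce] * freqs[cs:ce].max(axis=1)).sum())
    min_core = float((info[cs:ce] * freqs[cs:ce].min(axis=1)).sum())

    seq = sequence.upper()
    codes_fwd = np.array([BASE_INDEX.get(b, -1) for b in seq], dtype=np.intp)
    # reverse complement of the forward code: A<->T, C<->G is 3 - code;
    # keep the non-ACGT sentinel (-1) intact
    codes_rc_full = np.where(codes_fwd >= 0, 3 - codes_fwd, -1)[::-1]

    hits: list[TFBEHit] = []
    weights = freqs * info[:, None]  # (L, 4)

    def strand_scores(codes: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        # sliding windows (n, L) of base codes
        win = np.lib.stride_tricks.sliding_window_view(codes, L)
        valid = (win >= 0).all(axis=1)
        safe = np.where(win >= 0, win, 0)
        pos = np.arange(L)
        cur_full = weights[pos, safe].sum(axis=1)
        cur_core = weights[pos[cs:ce], safe[:, cs:ce]].sum(axis=1)
        mss = (
            np.zeros(len(win))
            if max_full == min_full
            else (cur_full - min_full) / (max_full - min_full)
        )
        css = (
            np.zeros(len(win))
            if max_core == min_core
            else (cur_core - min_core) / (max_core - min_core)
        )
        return mss, css, valid

    mss_f, css_f, ok_f = strand_scores(codes_fwd)
    mss_r, css_r, ok_r = strand_scores(codes_rc_full)

    for i in range(n):
        if ok_f[i] and css_f[i] >= core_cutoff and mss_f[i] >= matrix_cutoff:
            hits.append(
                TFBEHit(
                    region_id, pwm.name, chrom, offset + i, "+",
                    float(css_f[i]), float(mss_f[i]), seq[i : i + L],
                )
            )
        # window starting at forward position i corresponds to reverse-scan
        # window starting at n - 1 - i in the reversed-complemented codes
        j = n - 1 - i
        if ok_r[j] and css_r[j] >= core_cutoff and mss_r[j] >= matrix_cutoff:
            hits.append(
                TFBEHit(
                    region_id, pwm.name, chrom, offset + i, "-",
                    float(css_r[j]), float(mss_r[j]),
                    reverse_complement(seq[i : i + L]),
                )
            )
    return hits


def scan(
    pwm: PWM,
    region: GenomicInterval,
    genome,
    core_cutoff: float = DEFAULT_CORE_CUTOFF,
    matrix_cutoff: float = DEFAULT_MATRIX_CUTOFF,
    region_id: str | None = None,
) -> list[TFBEHit]:
    """Scan a genomic region (both strands) for binding elements."""
    seq = genome.fetch(region)
    rid = region_id or f"{region.chrom}:{region.start}-{region.end}"
    return scan_sequence(
        pwm,
        seq,
        core_cutoff=core_cutoff,
        matrix_cutoff=matrix_cutoff,
        region_id=rid,
        chrom=region.chrom,
        offset=region.start,
    )
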