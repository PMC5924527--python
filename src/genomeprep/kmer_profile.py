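"""Canonical k-mer histograms and spectrum-based genome profiling.

The multiplicity spectrum of k-mers from a deep whole-genome read set has a
characteristic shape: a large peak near multiplicity 1 from sequencing
errors, a main peak at the k-mer coverage depth λ from single-copy diploid
sequence, an optional heterozygosity peak near λ/2, and duplication /
triplication peaks near 2λ and 3λ.  Genome size follows from the total
k-mer mass above the error cutoff divided by λ.

Counting is canonical (a k-mer and its reverse complement are the same
object) so the histogram is invariant to read strand.  Two counter backends
share one contract: a vectorised integer-encoding backend (default) and a
plain dictionary backend.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional, Union

import numpy as np

from .formats import Read, revcomp

PathLike = Union[str, Path]


@dataclass
class SpectrumConfig:
    k: int = 23
    smoothing_window: int = 5  # odd, bins
    multiplicity_cap: int = 10000
    peak_tolerance: float = 0.12  # relative, for matching 0.5x/2x/3x positions
    min_secondary_fraction: float = 0.005  # of main-peak height, noise floor

    def __post_init__(self) -> None:
        if self.k < 3:
            raise ValueError("k must be >= 3")
        if self.smoothing_window < 1 or self.smoothing_window % 2 == 0:
            raise ValueError("smoothing_window must be a positive odd integer")


@dataclass
class KmerHistogram:
    """multiplicity m -> number of distinct k-mers observed m times."""

    counts: dict[int, int]

    def __post_init__(self) -> None:
        if any(m < 1 for m in self.counts):
            raise ValueError("multiplicities must be >= 1")

    @property
    def total_kmers(self) -> int:
        """Total counted k-mer instances, Σ m·f(m)."""
        return sum(m * f for m, f in self.counts.items())

    @property
    def distinct_kmers(self) -> int:
        return sum(self.counts.values())

    def as_array(self) -> np.ndarray:
        """Dense f(m) for m = 0..max (index 0 unused, kept 0)."""
        mmax = max(self.counts)
        arr = np.zeros(mmax + 1, dtype=float)
        for m, f in self.counts.items():
            arr[m] = f
        return arr


# ---------------------------------------------------------------------------
# counting


def _count_codes_array(sequences: Iterable[str], k: int) -> np.ndarray:
    """Canonical k-mer codes of all N-free windows, via 2-bit integer codes.

    Sequences are concatenated with an 'N' separator so windows never span a
    read boundary; any window containing a non-ACGT base is excluded.
    """
    blob = "N".join(sequences)
    if len(blob) < k:
        return np.empty(0, dtype=np.int64)
    table = np.full(256, -1, dtype=np.int8)
    for i, b in enumerate("ACGT"):
        table[ord(b)] = i
    base = table[np.frombuffer(blob.encode("ascii"), dtype=np.uint8)].astype(np.int64)
    n = len(base)
    invalid = base < 0
    safe = np.where(invalid, 0, base)
    nwin = n - k + 1
    fwd = np.zeros(nwin, dtype=np.int64)
    rev = np.zeros(nwin, dtype=np.int64)
    for j in range(k):
        fwd += safe[j : nwin + j] << (2 * (k - 1 - j))
        rev += (3 - safe[j : nwin + j]) << (2 * j)
    bad = np.cumsum(np.concatenate(([0], invalid.astype(np.int64))))
    valid = (bad[k:] - bad[:-k]) == 0
    return np.minimum(fwd, rev)[valid]


def count_kmers(
    reads: Iterable[Read],
    config: Optional[SpectrumConfig] = None,
    backend: str = "array",
) -> KmerHistogram:
    """Canonical k-mer multiplicity histogram over a read set.

    k-mers containing N are skipped; multiplicities above ``multiplicity_cap``
    are binned at the cap.  ``backend`` selects 'array' (vectorised, default)
    or 'dict' (plain hash map; reference behaviour, slower).
    """
    config = config or SpectrumConfig()
    k = config.k
    sequences = (r.sequence if isinstance(r, Read) else str(r) for r in reads)
    if backend == "array":
        codes = _count_codes_array((s.upper() for s in sequences), k)
        if codes.size == 0:
            raise ValueError(f"no countable {k}-mer in input")
        _, mults = np.unique(codes, return_counts=True)
        mults = np.minimum(mults, config.multiplicity_cap)
        ms, fs = np.unique(mults, return_counts=True)
        return KmerHistogram({int(m): int(f) for m, f in zip(ms, fs)})
    if backend == "dict":
        table: dict[str, int] = {}
        for seq in sequences:
            seq = seq.upper()
            for i in range(len(seq) - k + 1):
                kmer = seq[i : i + k]
                if "N" in kmer:
                    continue
                rc = revcomp(kmer)
                canon = kmer if kmer <= rc else rc
                table[canon] = table.get(canon, 0) + 1
        if not table:
            raise ValueError(f"no countable {k}-mer in input")
        hist: dict[int, int] = {}
        for mult in table.values():
            m = min(mult, config.multiplicity_cap)
            hist[m] = hist.get(m, 0) + 1
        return KmerHistogram(hist)
    raise ValueError(f"unknown backend {backend!r}")


# ---------------------------------------------------------------------------
# spectrum analysis


class PeakClass:
    HET = "HET"  # ~0.5x main depth: heterozygous positions
    DUP = "DUP"  # ~2x: duplicated sequence
    TRIP = "TRIP"  # ~3x: triplicated sequence


@dataclass
class SpectrumModel:
    error_cutoff: int
    main_peak: int
    secondary_peaks: list[tuple[int, str]] = field(default_factory=list)
    genome_size: Optional[int] = None
    heterozygous_peak_detected: bool = False

    def __post_init__(self) -> None:
        if self.error_cutoff >= self.main_peak:
            raise ValueError("error_cutoff must precede main_peak")


def _smooth(arr: np.ndarray, window: int) -> np.ndarray:
    """Centred moving average with edge truncation."""
    if window == 1:
        return arr.astype(float)
    kernel = np.ones(window)
    num = np.convolve(arr, kernel, mode="same")
    den = np.convolve(np.ones_like(arr, dtype=float), kernel, mode="same")
    return num / den


def fit_spectrum(hist: KmerHistogram, config: Optional[SpectrumConfig] = None) -> SpectrumModel:
    """Locate error cutoff, main coverage peak and secondary peaks.

    The dense spectrum f(m) is smoothed with a centred moving average; the
    error cutoff is the first local minimum after m = 1 (first strict rise of
    the smoothed curve), the main peak λ is the argmax beyond the cutoff, and
    secondary peaks are local maxima lying within ``peak_tolerance`` of
    0.5λ (HET), 2λ (DUP) or 3λ (TRIP) with height above the noise floor.
    """
    config = config or SpectrumConfig()
    if len(hist.counts) < 2:
        raise ValueError("histogram degenerate: fewer than 2 occupied multiplicities")
    f = hist.as_array()  # index = multiplicity
    # smooth over m >= 1 only: m = 0 is not a multiplicity, and letting the
    # window treat it as an observed zero manufactures a rise at the origin
    body = _smooth(f[1:], config.smoothing_window)
    fs = np.concatenate(([body[0]], body))
    # first local minimum after m=1: first m >= 1 where the smoothed curve rises
    cutoff = None
    for m in range(1, len(fs) - 1):
        if fs[m + 1] > fs[m]:
            cutoff = m
            break
    if cutoff is None:
        raise ValueError(
            "spectrum is monotone: no error/signal valley found; coverage may be too shallow"
        )
    tail = fs[cutoff + 1 :]
    if tail.size == 0:
        raise ValueError("no multiplicities beyond the error cutoff")
    main_peak = int(np.argmax(tail)) + cutoff + 1
    main_height = fs[main_peak]

    # local maxima beyond the cutoff (excluding the main peak itself)
    secondary: list[tuple[int, str]] = []
    floor = config.min_secondary_fraction * main_height
    targets = ((0.5, PeakClass.HET), (2.0, PeakClass.DUP), (3.0, PeakClass.TRIP))
    for m in range(cutoff + 1, len(fs) - 1):
        if m == main_peak or fs[m] < floor:
            continue
        if fs[m] > fs[m - 1] and fs[m] >= fs[m + 1]:
            for ratio, label in targets:
                expect = ratio * main_peak
                if abs(m - expect) <= config.peak_tolerance * expect:
                    secondary.append((m, label))
                    break
    het = any(label == PeakClass.HET for _, label in secondary)
    return SpectrumModel(
        error_cutoff=cutoff,
        main_peak=main_peak,
        secondary_peaks=secondary,
        heterozygous_peak_detected=het,
    )


def estimate_genome_size(hist: KmerHistogram, model: SpectrumModel) -> int:
    """Genome size = Σ_{m > cutoff} m·f(m) / λ, rounded to the nearest bp.

    Excluding the sub-cutoff region removes the error k-mer mass; repetitive
    sequence contributes proportionally to its copy number, as it should.
    For reads of length L at base coverage C, λ ≈ C·(L−k+1)/L.
    """
    if model.main_peak <= 0:
        raise ValueError("main peak multiplicity must be positive")
    mass = sum(m * f for m, f in hist.counts.items() if m > model.error_cutoff)
    size = int(round(mass / model.main_peak))
    model.genome_size = size
    return size


def profile(hist: KmerHistogram, config: Optional[SpectrumConfig] = None) -> SpectrumModel:
    """fit_spectrum + estimate_genome_size in one call."""
    model = fit_spectrum(hist, config)
    estimate_genome_size(hist, model)
    return model


# ---------------------------------------------------------------------------
# histogram I/O (2-column TSV: multiplicity, count)


def write_histogram(hist: KmerHistogram, dest: PathLike) -> None:
    with open(dest, "w") as fh:
        for m in sorted(hist.counts):
            fh.write(f"{m}\t{hist.counts[m]}\n")


def read_histogram(source: PathLike) -> KmerHistogram:
    counts: dict[int, int] = {}
    with open(source) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            m, f = line.split("\t")[:2]
            counts[int(m)] = counts.get(int(m), 0) + int(f)
    return KmerHistogram(counts)
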