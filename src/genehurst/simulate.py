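"""Synthetic long-memory data: fGn, DNA-like series, whole synthetic genomes.

Fractional Gaussian noise (fGn) is the canonical stationary long-memory
model: a Gaussian process with autocovariance

    gamma(k) = sigma^2 / 2 * (|k+1|^(2H) - 2|k|^(2H) + |k-1|^(2H)),

which decays like k^(2H-2).  Series are synthesized with the Davies-Harte
circulant-embedding method, which is exact in distribution for all
H in (0, 1).

On top of the generator this module builds DNA-like test material:
quartile-coarsened 4-letter series with a known target H, and complete
synthetic genomes (FASTA + gene table + truth sidecar) whose "essential"
and "nonessential" gene groups draw their per-gene H from configurable
distributions.  These genomes are the verification bed for the whole
pipeline: parameter recovery replaces any dependence on downloads.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .codec import (
    DigitizedSequence,
    reverse_complement,
    undigitize,
)
from .exceptions import DomainError, EmbeddingError, InputError

logger = logging.getLogger(__name__)

#: eigenvalues of the circulant embedding below this are a covariance bug
_EIGEN_TOL = 1e-8


def fgn_autocovariance(H: float, sigma: float, k) -> np.ndarray | float:
    """Exact fGn autocovariance at lag(s) ``k``.

    gamma(k) = sigma^2/2 (|k+1|^{2H} - 2|k|^{2H} + |k-1|^{2H}); equals
    sigma^2 at k = 0.
    """
    if not 0 < H <= 1:
        raise DomainError(f"H must be in (0, 1], got {H}")
    if sigma <= 0:
        raise DomainError(f"sigma must be > 0, got {sigma}")
    karr = np.abs(np.asarray(k, dtype=float))
    out = (
        sigma**2
        / 2.0
        * ((karr + 1) ** (2 * H) - 2 * karr ** (2 * H) + np.abs(karr - 1) ** (2 * H))
    )
    return float(out) if np.isscalar(k) else out


@dataclass(frozen=True)
class FGnSpec:
    """Specification of one fGn realization."""

    H: float
    length: int
    sigma: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.H < 1:
            raise DomainError(f"H must be in (0, 1), got {self.H}")
        if self.length < 2:
            raise DomainError("length must be >= 2")
        if self.sigma <= 0:
            raise DomainError("sigma must be > 0")


def simulate_fgn(spec: FGnSpec, rng: np.random.Generator | None = None) -> np.ndarray:
    """Davies-Harte exact simulation of fractional Gaussian noise.

    The autocovariance is embedded in a circulant matrix whose eigenvalues
    come from one FFT; for fGn these are non-negative for every H in (0,1),
    so any eigenvalue below ``-1e-8`` signals a covariance bug and raises.
    Tiny negative eigenvalues from floating-point roundoff are clipped to
    zero with a logged warning.  Deterministic for a given seed.
    """
    n = spec.length
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    # embedding size: next power of two >= n keeps the FFT fast and exact
    m = 1 << int(np.ceil(np.log2(n))) if n > 1 else 2
    acov = fgn_autocovariance(spec.H, spec.sigma, np.arange(m + 1))
    row = np.concatenate([acov, acov[-2:0:-1]])  # circular, length 2m
    eig = np.fft.rfft(row).real
    if eig.min() < -_EIGEN_TOL:
        raise EmbeddingError(
            f"circulant embedding eigenvalue {eig.min():.3e} < -{_EIGEN_TOL}"
        )
    if eig.min() < 0:
        logger.warning(
            "clipping %d slightly negative embedding eigenvalues (min %.3e)",
            int((eig < 0).sum()), eig.min(),
        )
        eig = np.clip(eig, 0.0, None)
    two_m = 2 * m
    # complex Gaussian weights: real at DC and Nyquist, complex elsewhere
    z = rng.standard_normal(m + 1) + 1j * rng.standard_normal(m + 1)
    z[0] = z[0].real * np.sqrt(2.0)
    z[-1] = z[-1].real * np.sqrt(2.0)
    weights = np.sqrt(eig / (2.0 * two_m)) * z
    sample = np.fft.irfft(weights, two_m) * two_m
    return sample[:n]


def fgn_to_dna(series: np.ndarray, source_id: str = "") -> DigitizedSequence:
    """Coarsen a real series into 4 ordered symbol classes by its quartiles.

    Ranks are split into four equal classes (up to rounding) mapped to the
    digits 0..3; the monotone rank map preserves the ordering structure, so
    long-range dependence survives the coarsening (the attainable H after
    coarsening is verified empirically, not assumed exact).
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1 or x.size < 4:
        raise InputError("series must be 1-d with length >= 4")
    if np.all(x == x[0]):
        raise DomainError("all values identical; quartile classes undefined")
    order = np.argsort(x, kind="stable")
    ranks = np.empty(x.size, dtype=np.int64)
    ranks[order] = np.arange(x.size)
    digits = (ranks * 4) // x.size
    return DigitizedSequence(source_id=source_id, values=digits.astype(np.int8))


# ---------------------------------------------------------------------------
# distribution descriptors for the genome generator


@dataclass(frozen=True)
class TruncatedNormal:
    """Normal(mean, sd) conditioned on (low, high)."""

    mean: float
    sd: float
    low: float = 0.05
    high: float = 0.95

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        out = np.empty(n)
        filled = 0
        while filled < n:
            draw = rng.normal(self.mean, self.sd, size=2 * (n - filled) + 16)
            draw = draw[(draw > self.low) & (draw < self.high)]
            take = min(draw.size, n - filled)
            out[filled : filled + take] = draw[:take]
            filled += take
        return out


@dataclass(frozen=True)
class NormalMixture:
    """Finite mixture of truncated normals (weights sum to 1)."""

    components: tuple[tuple[float, TruncatedNormal], ...]

    def __post_init__(self):
        total = sum(w for w, _ in self.components)
        if not np.isclose(total, 1.0):
            raise DomainError(f"mixture weights sum to {total}, expected 1")

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        weights = np.array([w for w, _ in self.components])
        choice = rng.choice(len(self.components), size=n, p=weights)
        out = np.empty(n)
        for i, (_, comp) in enumerate(self.components):
            mask = choice == i
            if mask.any():
                out[mask] = comp.sample(int(mask.sum()), rng)
        return out


@dataclass(frozen=True)
class LogNormalLength:
    """Log-normal gene-length model, clipped to [minimum, maximum] bases."""

    median: float = 900.0
    sigma: float = 0.55
    minimum: int = 150
    maximum: int = 6000

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        draw = rng.lognormal(mean=np.log(self.median), sigma=self.sigma, size=n)
        return np.clip(np.round(draw), self.minimum, self.maximum).astype(int)


#: H distribution of the "essential" group: unimodal truncated normal
DEFAULT_ESSENTIAL_H = TruncatedNormal(mean=0.62, sd=0.04)
#: H distribution of the "nonessential" group: bimodal mixture.  The mode
#: separation (0.32) is sized so the bimodality remains detectable after
#: per-gene estimation noise at the default gene-length scale (sd ~ 0.07-0.1
#: for the smoothed spectral mode on ~900-base genes); a smaller separation
#: is washed out by that noise and the group contrast becomes a coin flip.
DEFAULT_NONESSENTIAL_H = NormalMixture(
    components=(
        (0.5, TruncatedNormal(mean=0.52, sd=0.03)),
        (0.5, TruncatedNormal(mean=0.84, sd=0.05)),
    )
)


@dataclass(frozen=True)
class SyntheticGenomeSpec:
    """Parameters of a synthetic genome with labelled gene groups."""

    n_essential: int = 50
    n_nonessential: int = 200
    essential_h_dist: TruncatedNormal | NormalMixture = DEFAULT_ESSENTIAL_H
    nonessential_h_dist: TruncatedNormal | NormalMixture = DEFAULT_NONESSENTIAL_H
    gene_length_dist: LogNormalLength = field(default_factory=LogNormalLength)
    replicon_id: str = "SYN_REPLICON_1"
    spacer_range: tuple[int, int] = (20, 200)
    seed: int = 0

    def __post_init__(self):
        if self.n_essential < 0 or self.n_nonessential < 0:
            raise DomainError("gene counts must be non-negative")
        if self.n_essential + self.n_nonessential < 1:
            raise InputError("spec must request at least one gene")


@dataclass(frozen=True)
class SyntheticGenome:
    """In-memory result of :func:`generate_genome`."""

    replicon_id: str
    residues: str
    gene_rows: tuple[dict, ...]  # gene_id, start, end, strand, essentiality
    truth: tuple[dict, ...]      # gene_id, true_H, group, coding sequence

    def write(self, fasta_path: str | Path, gene_table_path: str | Path,
              truth_path: str | Path | None = None) -> None:
        fasta_path, gene_table_path = Path(fasta_path), Path(gene_table_path)
        with open(fasta_path, "w") as fh:
            fh.write(f">{self.replicon_id} synthetic\n")
            for i in range(0, len(self.residues), 70):
                fh.write(self.residues[i : i + 70] + "\n")
        with open(gene_table_path, "w") as fh:
            fh.write("gene_id\treplicon_id\tstart\tend\tstrand\tessentiality\n")
            for row in self.gene_rows:
                fh.write(
                    f"{row['gene_id']}\t{self.replicon_id}\t{row['start']}\t"
                    f"{row['end']}\t{row['strand']}\t{row['essentiality']}\n"
                )
        if truth_path is not None:
            with open(truth_path, "w") as fh:
                fh.write("gene_id\ttrue_H\tgroup\n")
                for row in self.truth:
                    fh.write(f"{row['gene_id']}\t{row['true_H']:.6f}\t{row['group']}\n")


def generate_genome(spec: SyntheticGenomeSpec) -> SyntheticGenome:
    """Build a synthetic genome with controlled per-gene Hurst exponents.

    Per gene: draw a target H from the gene's group distribution and a
    length from the length model, synthesize an fGn of that length and H,
    quartile-coarsen it to digits, and un-digitize to an A/G/C/T string.
    Genes are concatenated with short iid-digit spacers (no long-range
    structure) into one replicon.  Minus-strand genes are stored
    reverse-complemented, so coordinate extraction followed by reverse
    complementation recovers the generated coding sequence exactly.
    """
    rng = np.random.default_rng(spec.seed)
    labels = ["essential"] * spec.n_essential + ["nonessential"] * spec.n_nonessential
    n_genes = len(labels)
    h_ess = spec.essential_h_dist.sample(spec.n_essential, rng)
    h_non = spec.nonessential_h_dist.sample(spec.n_nonessential, rng)
    h_all = np.concatenate([h_ess, h_non])
    lengths = spec.gene_length_dist.sample(n_genes, rng)
    strands = rng.choice(["+", "-"], size=n_genes)

    pieces: list[str] = []
    gene_rows: list[dict] = []
    truth: list[dict] = []
    cursor = 0  # 0-based running genome length

    def spacer() -> str:
        length = int(rng.integers(spec.spacer_range[0], spec.spacer_range[1] + 1))
        return undigitize(rng.integers(0, 4, size=length))

    for i in range(n_genes):
        gap = spacer()
        pieces.append(gap)
        cursor += len(gap)
        fgn = simulate_fgn(
            FGnSpec(H=float(h_all[i]), length=int(lengths[i]), seed=0), rng=rng
        )
        coding = undigitize(fgn_to_dna(fgn).values)
        stored = reverse_complement(coding) if strands[i] == "-" else coding
        start = cursor + 1  # 1-based inclusive
        end = cursor + len(stored)
        pieces.append(stored)
        cursor = end
        gene_id = f"g{i + 1:05d}"
        gene_rows.append(
            {
                "gene_id": gene_id,
                "start": start,
                "end": end,
                "strand": str(strands[i]),
                "essentiality": labels[i],
            }
        )
        truth.append(
            {"gene_id": gene_id, "true_H": float(h_all[i]), "group": labels[i],
             "coding": coding}
        )
    pieces.append(spacer())
    return SyntheticGenome(
        replicon_id=spec.replicon_id,
        residues="".join(pieces),
        gene_rows=tuple(gene_rows),
        truth=tuple(truth),
    )
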