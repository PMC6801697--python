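"""Nei-Gojobori (1986) Ka/Ks estimation and Ks-distribution analysis.

For a pair of aligned coding sequences the NG86 method counts, per codon,
the fraction of one-step nucleotide changes that are synonymous (the
codon's synonymous *sites*), and counts observed synonymous and
nonsynonymous *differences* by averaging over all minimal mutational
pathways between the two codons, excluding pathways that pass through a
stop codon.  The proportions ps = Sd/S and pn = Nd/N are corrected for
multiple hits with the Jukes-Cantor formula d = -(3/4) ln(1 - (4/3) p),
which saturates at p >= 3/4.

The distribution of Ks over many ortholog pairs carries signal about
divergence history: a single peak is expected for a single divergence
time, whereas a bimodal distribution (fit here with two-component normal
or gamma mixtures by EM) indicates heterogeneous synonymous divergence.
"""

from __future__ import annotations

import dataclasses
import itertools
import logging
import math
from typing import Sequence

import numpy as np
from Bio.Data import CodonTable
from scipy import stats
from scipy.optimize import brentq
from scipy.signal import find_peaks
from scipy.special import digamma, gammaln

logger = logging.getLogger(__name__)

_BASES = "ACGT"
_TABLE = CodonTable.unambiguous_dna_by_id[1]

CODON_TO_AA: dict[str, str] = dict(_TABLE.forward_table)
for _stop in _TABLE.stop_codons:
    CODON_TO_AA[_stop] = "*"
SENSE_CODONS: tuple[str, ...] = tuple(
    sorted(c for c, aa in CODON_TO_AA.items() if aa != "*")
)


def _neighbors(codon: str) -> list[tuple[str, bool]]:
    """One-step mutational neighbors of a codon with a synonymy flag.

    Changes to stop codons are returned with is_syn=False: NG86 counts
    them among the nonsynonymous site total.
    """
    out = []
    aa = CODON_TO_AA[codon]
    for pos in range(3):
        for b in _BASES:
            if b == codon[pos]:
                continue
            mut = codon[:pos] + b + codon[pos + 1 :]
            out.append((mut, CODON_TO_AA[mut] == aa and CODON_TO_AA[mut] != "*"))
    return out


_SYN_SITES: dict[str, float] = {
    c: sum(is_syn for _, is_syn in _neighbors(c)) / 3.0 for c in SENSE_CODONS
}


@dataclasses.dataclass
class CodonAlignment:
    """Two equal-length gapped CDSs; gaps only as whole codons '---'."""

    seq_a: str
    seq_b: str

    def __post_init__(self) -> None:
        a, b = self.seq_a.upper(), self.seq_b.upper()
        if len(a) != len(b):
            raise ValueError("aligned sequences differ in length")
        if len(a) % 3:
            raise ValueError("alignment length not a multiple of 3")
        for seq, name in ((a, "a"), (b, "b")):
            for i in range(0, len(seq), 3):
                codon = seq[i : i + 3]
                if "-" in codon and codon != "---":
                    raise ValueError(
                        f"sequence {name}: partial-codon gap at codon {i // 3 + 1}"
                    )
                if codon in _TABLE.stop_codons:
                    raise ValueError(
                        f"sequence {name}: internal stop at codon {i // 3 + 1}"
                    )
        self.seq_a, self.seq_b = a, b

    def comparable_codons(self) -> list[tuple[str, str]]:
        """Codon pairs with no gap and no ambiguous base in either."""
        pairs = []
        for i in range(0, len(self.seq_a), 3):
            ca, cb = self.seq_a[i : i + 3], self.seq_b[i : i + 3]
            if ca == "---" or cb == "---":
                continue
            if any(ch not in _BASES for ch in ca + cb):
                continue
            pairs.append((ca, cb))
        return pairs


def backtranslate(
    protein_a: str, protein_b: str, cds_a: str, cds_b: str
) -> CodonAlignment:
    """Thread CDSs onto an aligned protein pair (codon alignment).

    Each amino acid is replaced by its source codon and each protein gap
    by '---'.  The ungapped protein must equal the conceptual translation
    of its CDS (standard code, trailing stop stripped); a mismatch raises
    naming the codon position.
    """
    out = []
    for prot, cds, name in ((protein_a, cds_a, "a"), (protein_b, cds_b, "b")):
        prot = prot.upper()
        cds = cds.upper()
        if len(cds) % 3:
            raise ValueError(f"sequence {name}: CDS length not a multiple of 3")
        codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
        if codons and CODON_TO_AA.get(codons[-1]) == "*":
            codons = codons[:-1]
        n_aa = sum(1 for ch in prot if ch != "-")
        if n_aa != len(codons):
            raise ValueError(
                f"sequence {name}: protein has {n_aa} residues but CDS has "
                f"{len(codons)} codons"
            )
        aligned = []
        k = 0
        for ch in prot:
            if ch == "-":
                aligned.append("---")
                continue
            codon = codons[k]
            aa = CODON_TO_AA.get(codon)
            if aa == "*":
                raise ValueError(f"sequence {name}: internal stop at codon {k + 1}")
            if aa != ch:
                raise ValueError(
                    f"sequence {name}: codon {k + 1} mismatch "
                    f"({codon} translates to {aa}, protein has {ch})"
                )
            aligned.append(codon)
            k += 1
        out.append("".join(aligned))
    return CodonAlignment(out[0], out[1])


@dataclasses.dataclass
class KaKsEstimate:
    ka: float
    ks: float
    sites_s: float
    sites_n: float
    sd: float
    nd: float
    saturated: bool

    @property
    def ratio(self) -> float:
        """Ka/Ks; NaN when Ks = 0 (undefined) or the pair is saturated."""
        if self.saturated or self.ks == 0 or math.isnan(self.ks):
            return math.nan
        return self.ka / self.ks

    @property
    def n_codons(self) -> float:
        return (self.sites_s + self.sites_n) / 3.0


def _pathway_counts(ca: str, cb: str) -> tuple[float, float]:
    """Synonymous/nonsynonymous differences between two codons, averaged
    over all minimal mutational pathways that avoid stop codons."""
    diff_pos = [p for p in range(3) if ca[p] != cb[p]]
    if not diff_pos:
        return 0.0, 0.0
    valid: list[tuple[int, int]] = []
    fallback: list[tuple[int, int]] = []
    for order in itertools.permutations(diff_pos):
        cur = ca
        sd = nd = 0
        through_stop = False
        for pos in order:
            nxt = cur[:pos] + cb[pos] + cur[pos + 1 :]
            if CODON_TO_AA[nxt] == "*" and nxt != cb:
                through_stop = True
            if CODON_TO_AA[nxt] == CODON_TO_AA[cur] and CODON_TO_AA[nxt] != "*":
                sd += 1
            else:
                nd += 1
            cur = nxt
        (fallback if through_stop else valid).append((sd, nd))
    paths = valid or fallback  # all-stop pathways: fall back to the full set
    sd = sum(p[0] for p in paths) / len(paths)
    nd = sum(p[1] for p in paths) / len(paths)
    return sd, nd


def ng86(alignment: CodonAlignment) -> KaKsEstimate:
    """NG86 Ka/Ks with Jukes-Cantor correction.

    Symmetric in its two sequences.  sites_s + sites_n always equals
    3 x (number of comparable codons).  When ps or pn reaches 3/4 the
    corresponding rate is undefined; the estimate is flagged saturated
    and the rate reported as NaN.
    """
    codons = alignment.comparable_codons()
    if not codons:
        raise ValueError("no comparable codons in alignment")
    S = sum(_SYN_SITES[ca] + _SYN_SITES[cb] for ca, cb in codons) / 2.0
    N = 3.0 * len(codons) - S
    Sd = Nd = 0.0
    for ca, cb in codons:
        sd, nd = _pathway_counts(ca, cb)
        Sd += sd
        Nd += nd
    ps = Sd / S if S > 0 else 0.0
    pn = Nd / N if N > 0 else 0.0
    # boundary tolerance: p is a ratio of small rationals computed in
    # floats, so compare against 3/4 with rounding slack
    sat_s, sat_n = ps >= 0.75 - 1e-12, pn >= 0.75 - 1e-12
    saturated = sat_s or sat_n
    ks = math.nan if sat_s else _jukes_cantor(ps)
    ka = math.nan if sat_n else _jukes_cantor(pn)
    return KaKsEstimate(
        ka=ka, ks=ks, sites_s=S, sites_n=N, sd=Sd, nd=Nd, saturated=saturated
    )


def _jukes_cantor(p: float) -> float:
    return -0.75 * math.log1p(-4.0 * p / 3.0)


# ---------------------------------------------------------------------------
# Ks density


@dataclasses.dataclass
class KsDensity:
    grid: np.ndarray
    density: np.ndarray
    modes: np.ndarray  # x positions of local maxima

    @property
    def mode_count(self) -> int:
        return len(self.modes)


def ks_density(
    values: Sequence[float],
    bandwidth: float | str | None = "silverman",
    grid_points: int = 512,
    prominence_fraction: float = 0.05,
) -> KsDensity:
    """Gaussian kernel density of a Ks (or Ka/Ks) sample with mode calling.

    Local maxima of the evaluated curve whose prominence exceeds
    ``prominence_fraction`` of the density maximum are reported as modes.
    """
    x = np.asarray([v for v in values if np.isfinite(v)], dtype=float)
    if len(x) < 10:
        raise ValueError("need at least 10 finite values for a density")
    kde = stats.gaussian_kde(x, bw_method=bandwidth)
    h = math.sqrt(float(kde.covariance[0, 0]))
    grid = np.linspace(x.min() - 3 * h, x.max() + 3 * h, grid_points)
    dens = kde(grid)
    peaks, _ = find_peaks(dens, prominence=prominence_fraction * dens.max())
    return KsDensity(grid=grid, density=dens, modes=grid[peaks])


# ---------------------------------------------------------------------------
# Mixture fitting


@dataclasses.dataclass
class KsMixtureFit:
    family: str  # "normal" | "gamma"
    k_components: int
    weights: np.ndarray
    params: list[dict[str, float]]  # mean/sd or shape/scale per component
    log_likelihood: float
    aic: float
    bic: float
    bimodal: bool
    fallback: bool = False  # degenerate 2-component fit collapsed to 1

    @property
    def component_means(self) -> np.ndarray:
        if self.family == "normal":
            return np.array([p["mean"] for p in self.params])
        return np.array([p["shape"] * p["scale"] for p in self.params])

    @property
    def component_sds(self) -> np.ndarray:
        if self.family == "normal":
            return np.array([p["sd"] for p in self.params])
        return np.array(
            [math.sqrt(p["shape"]) * p["scale"] for p in self.params]
        )


def _logpdf(x: np.ndarray, family: str, p: dict[str, float]) -> np.ndarray:
    if family == "normal":
        return stats.norm.logpdf(x, loc=p["mean"], scale=p["sd"])
    a, s = p["shape"], p["scale"]
    return (a - 1) * np.log(x) - x / s - gammaln(a) - a * np.log(s)


def _gamma_mle(x: np.ndarray, w: np.ndarray) -> dict[str, float]:
    """Weighted gamma MLE; the shape solves log(a) - digamma(a) = c."""
    wsum = w.sum()
    mean = float((w * x).sum() / wsum)
    mean_log = float((w * np.log(x)).sum() / wsum)
    c = math.log(mean) - mean_log
    if c <= 1e-12:  # near-degenerate sample
        c = 1e-12
    shape = brentq(lambda a: math.log(a) - digamma(a) - c, 1e-3, 1e7)
    return {"shape": float(shape), "scale": mean / shape}


def _normal_mle(x: np.ndarray, w: np.ndarray) -> dict[str, float]:
    wsum = w.sum()
    mean = float((w * x).sum() / wsum)
    var = float((w * (x - mean) ** 2).sum() / wsum)
    return {"mean": mean, "sd": math.sqrt(max(var, 1e-12))}


def _fit_single(x: np.ndarray, family: str) -> tuple[list[dict], float]:
    w = np.ones_like(x)
    p = _normal_mle(x, w) if family == "normal" else _gamma_mle(x, w)
    ll = float(_logpdf(x, family, p).sum())
    return [p], ll


def _em_two(
    x: np.ndarray,
    family: str,
    split_q: float,
    tol: float,
    max_iter: int,
) -> tuple[np.ndarray, list[dict], float]:
    """EM for a 2-component mixture from a quantile-split initialization."""
    cut = np.quantile(x, split_q)
    lower, upper = x[x <= cut], x[x > cut]
    if len(lower) < 2 or len(upper) < 2:
        raise RuntimeError("degenerate initialization split")
    mle = _normal_mle if family == "normal" else _gamma_mle
    params = [mle(lo, np.ones_like(lo)) for lo in (lower, upper)]
    weights = np.array([len(lower), len(upper)], dtype=float) / len(x)
    ll_prev = -np.inf
    for _ in range(max_iter):
        logp = np.stack(
            [np.log(weights[j]) + _logpdf(x, family, params[j]) for j in (0, 1)]
        )
        m = logp.max(axis=0)
        lse = m + np.log(np.exp(logp - m).sum(axis=0))
        ll = float(lse.sum())
        # EM guarantees monotone likelihood; tolerate only rounding error
        assert ll >= ll_prev - 1e-8, "EM log-likelihood decreased"
        resp = np.exp(logp - lse)
        weights = resp.sum(axis=1) / len(x)
        if weights.min() < 1e-3:
            raise RuntimeError("degenerate component weight")
        params = [mle(x, resp[j]) for j in (0, 1)]
        if abs(ll - ll_prev) < tol:
            break
        ll_prev = ll
    return weights, params, ll


def fit_ks_mixture(
    values: Sequence[float],
    family: str = "gamma",
    k: int = 2,
    restarts: int = 20,
    tol: float = 1e-8,
    max_iter: int = 2000,
    seed: int | None = None,
    method: str = "em",
) -> KsMixtureFit:
    """Fit a one- or two-component normal/gamma mixture to Ks values.

    The two-component fit takes the best of ``restarts`` random
    quantile-split initializations.  ``bimodal`` is set (k=2 only) when
    the 2-component AIC beats the 1-component AIC by more than 2 *and*
    the component means are separated by more than twice the larger
    component standard deviation.  method="binned" replaces EM with
    least squares on the histogram density, for cross-checking.
    """
    x = np.asarray([v for v in values if np.isfinite(v)], dtype=float)
    if len(x) < 30:
        raise ValueError("need at least 30 values to fit a mixture")
    if family not in ("normal", "gamma"):
        raise ValueError(f"unknown family {family!r}")
    if family == "gamma" and (x <= 0).any():
        raise ValueError("gamma mixture requires strictly positive values")
    if k not in (1, 2):
        raise ValueError("k must be 1 or 2")

    params1, ll1 = _fit_single(x, family)
    aic1 = 2 * 2 - 2 * ll1
    if k == 1:
        return KsMixtureFit(
            family=family,
            k_components=1,
            weights=np.array([1.0]),
            params=params1,
            log_likelihood=ll1,
            aic=aic1,
            bic=2 * math.log(len(x)) - 2 * ll1,
            bimodal=False,
        )

    if method == "binned":
        weights, params, ll = _binned_two(x, family)
        fallback = False
    else:
        rng = np.random.default_rng(seed)
        best = None
        failures = 0
        for _ in range(restarts):
            q = rng.uniform(0.2, 0.8)
            try:
                w, p, ll = _em_two(x, family, q, tol, max_iter)
            except RuntimeError:
                failures += 1
                continue
            if best is None or ll > best[2]:
                best = (w, p, ll)
        if best is None:
            if failures == restarts:
                logger.warning(
                    "all %d EM restarts degenerate; falling back to k=1", restarts
                )
                return dataclasses.replace(
                    fit_ks_mixture(x, family, 1), fallback=True
                )
            raise RuntimeError("EM failed in all restarts")
        weights, params, ll = best
        fallback = False

    # order components by mean
    order = np.argsort(
        [p["mean"] if family == "normal" else p["shape"] * p["scale"] for p in params]
    )
    weights = np.asarray(weights)[order]
    params = [params[i] for i in order]

    aic2 = 2 * 5 - 2 * ll
    fit = KsMixtureFit(
        family=family,
        k_components=2,
        weights=weights,
        params=params,
        log_likelihood=ll,
        aic=aic2,
        bic=5 * math.log(len(x)) - 2 * ll,
        bimodal=False,
        fallback=fallback,
    )
    sep = abs(fit.component_means[1] - fit.component_means[0])
    fit.bimodal = bool(aic1 - aic2 > 2 and sep > 2 * fit.component_sds.max())
    return fit


def _binned_two(
    x: np.ndarray, family: str, bins: int = 50
) -> tuple[np.ndarray, list[dict], float]:
    """Least-squares mixture fit on the binned empirical density."""
    from scipy.optimize import least_squares

    dens, edges = np.histogram(x, bins=bins, density=True)
    mid = 0.5 * (edges[:-1] + edges[1:])

    def unpack(theta):
        w = 1.0 / (1.0 + math.exp(-theta[0]))
        if family == "normal":
            p = [
                {"mean": theta[1], "sd": math.exp(theta[2])},
                {"mean": theta[3], "sd": math.exp(theta[4])},
            ]
        else:
            p = [
                {"shape": math.exp(theta[1]), "scale": math.exp(theta[2])},
                {"shape": math.exp(theta[3]), "scale": math.exp(theta[4])},
            ]
        return np.array([w, 1 - w]), p

    def resid(theta):
        w, p = unpack(theta)
        model = w[0] * np.exp(_logpdf(mid, family, p[0])) + w[1] * np.exp(
            _logpdf(mid, family, p[1])
        )
        return model - dens

    lo, hi = np.quantile(x, [0.25, 0.75])
    if family == "normal":
        theta0 = [0.0, lo, math.log(x.std() / 2), hi, math.log(x.std() / 2)]
    else:
        theta0 = [0.0, math.log(4.0), math.log(lo / 4.0), math.log(4.0),
                  math.log(hi / 4.0)]
    sol = least_squares(resid, theta0)
    w, p = unpack(sol.x)
    logp = np.stack(
        [np.log(w[j]) + _logpdf(x, family, p[j]) for j in (0, 1)]
    )
    m = logp.max(axis=0)
    ll = float((m + np.log(np.exp(logp - m).sum(axis=0))).sum())
    return w, p, ll
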