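"""Promoter-trap reporter simulation on annotated genomes.

The model: a genomic library is built from randomly sheared fragments cloned
(in either orientation) upstream of a reporter gene.  A clone fluoresces when
transcription traverses the reporter-proximal end of its insert.  Two vector
modes are simulated:

* ``promoterless`` — the trap proper: the reporter fires only if the insert
  contains a recognized promoter on the sense strand (the genome strand that
  reads toward the reporter under the insert's orientation) with no
  sense-strand terminator strictly between it and the reporter-proximal end.
* ``upstream_promoter`` — the induction control: a vector promoter upstream
  of the insert drives transcription, so the reporter fires unless a
  sense-strand terminator lies inside the insert.  With ``internal_rescue``
  a recognized promoter downstream of the last blocking terminator refires
  transcription.

Sigma-factor promoter recognition is a property of each promoter (all, none,
an explicit subset, or an independent Bernoulli draw per promoter), modelling
which promoters the host RNA polymerase — optionally armed with a
heterologous sigma factor — can fire.

The reporter-positive fraction of a library is computed two ways that must
agree: exact enumeration of every (start, orientation) placement at fixed
insert length, and seeded Monte Carlo over sheared inserts.  Both share one
vectorized classification core.

Boundary conventions (0-based half-open intervals): a point feature at
position p lies inside insert [s, e) iff s <= p < e; a terminator exactly at
the reporter-proximal boundary does not block (strict betweenness).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from statsmodels.stats.proportion import proportion_confint

from .annotation_io import FORWARD, REVERSE, GenomeAnnotation

ORIENT_A = "A"  # genome '+' strand reads toward the reporter
ORIENT_B = "B"  # genome '-' strand reads toward the reporter


# ---------------------------------------------------------------------------
# parameter objects


@dataclass(frozen=True)
class FragmentLengthModel:
    """Distribution of sheared-fragment lengths.

    ``fixed`` yields every fragment at ``mean_bp``; ``truncated_normal``
    resamples a normal(mean_bp, sd_bp) until it lands in [min_bp, max_bp],
    emulating gel-purified shearing bands (default band 200-1,000 bp).
    """

    kind: str = "fixed"
    mean_bp: float = 726.0
    sd_bp: float = 0.0
    min_bp: int = 200
    max_bp: int = 1000

    def __post_init__(self) -> None:
        if self.kind not in ("fixed", "truncated_normal"):
            raise ValueError(f"unknown length model kind {self.kind!r}")
        if not (self.min_bp <= self.mean_bp <= self.max_bp):
            raise ValueError("require min_bp <= mean_bp <= max_bp")
        if self.sd_bp < 0:
            raise ValueError("sd_bp must be >= 0")

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.kind == "fixed" or self.sd_bp == 0:
            return np.full(n, int(round(self.mean_bp)), dtype=np.int64)
        out = np.empty(n, dtype=np.int64)
        filled = 0
        while filled < n:
            draw = rng.normal(self.mean_bp, self.sd_bp, size=(n - filled) * 2 + 16)
            draw = np.rint(draw).astype(np.int64)
            ok = draw[(draw >= self.min_bp) & (draw <= self.max_bp)]
            take = min(ok.size, n - filled)
            out[filled:filled + take] = ok[:take]
            filled += take
        return out


@dataclass(frozen=True)
class Insert:
    """A sheared fragment: start offset, length, and cloning orientation."""

    start: int
    length: int
    orientation: str  # 'A' or 'B'

    def __post_init__(self) -> None:
        if self.orientation not in (ORIENT_A, ORIENT_B):
            raise ValueError("orientation must be 'A' or 'B'")
        if self.start < 0 or self.length < 1:
            raise ValueError("require start >= 0 and length >= 1")

    @property
    def end(self) -> int:
        """Unwrapped exclusive end; may exceed the genome length on circular genomes."""
        return self.start + self.length


@dataclass(frozen=True)
class VectorMode:
    """Trap-vector configuration."""

    kind: str = "promoterless"
    internal_rescue: bool = False

    def __post_init__(self) -> None:
        if self.kind not in ("promoterless", "upstream_promoter"):
            raise ValueError(f"unknown vector mode {self.kind!r}")
        if self.internal_rescue and self.kind != "upstream_promoter":
            raise ValueError("internal_rescue is meaningful only for upstream_promoter")


@dataclass(frozen=True)
class SigmaRecognitionModel:
    """Which promoters the (engineered) host polymerase can fire.

    ``all``/``none`` are the two extremes; ``subset`` names recognized
    promoter ids explicitly; ``bernoulli`` materializes one seeded
    recognized/unrecognized draw per promoter (recognition is a promoter
    property, not a per-cell event).  For a fixed seed the bernoulli sets are
    nested in ``p_rec``, which makes the positive fraction monotone in the
    recognized fraction by construction.
    """

    kind: str = "all"
    recognized_ids: frozenset[str] = frozenset()
    p_rec: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("all", "none", "subset", "bernoulli"):
            raise ValueError(f"unknown sigma model kind {self.kind!r}")
        if not (0.0 <= self.p_rec <= 1.0):
            raise ValueError("p_rec must lie in [0, 1]")

    def resolve(self, genome: GenomeAnnotation) -> frozenset[str]:
        """Materialize the recognized promoter-id set for ``genome``."""
        all_ids = [p.id for p in genome.promoters()]
        if self.kind == "all":
            return frozenset(all_ids)
        if self.kind == "none":
            return frozenset()
        if self.kind == "subset":
            unknown = self.recognized_ids - set(all_ids)
            if unknown:
                raise ValueError(f"recognized_ids not in genome: {sorted(unknown)[:5]}")
            return frozenset(self.recognized_ids)
        rng = np.random.default_rng(self.seed)
        u = rng.random(len(all_ids))
        return frozenset(pid for pid, ui in zip(all_ids, u) if ui < self.p_rec)


@dataclass(frozen=True)
class ClassificationResult:
    """Outcome of classifying one insert."""

    gfp_positive: bool
    cause: str                       # 'promoter_fired' | 'read_through' | 'none'
    cause_id: str | None = None      # firing promoter id when cause == 'promoter_fired'
    blocking_terminator: str | None = None

    def __post_init__(self) -> None:
        if self.gfp_positive != (self.cause != "none"):
            raise ValueError("gfp_positive must hold exactly when cause != 'none'")


# ---------------------------------------------------------------------------
# genome feature index


class _StrandFeatures:
    """Sorted position arrays for one strand, duplicated by +G for wraparound."""

    def __init__(self, positions: Sequence[int], ids: Sequence[str], G: int, circular: bool):
        order = np.argsort(np.asarray(positions, dtype=np.int64), kind="stable")
        base = np.asarray(positions, dtype=np.int64)[order]
        self.ids = [ids[i] for i in order]
        self.n = base.size
        if circular:
            self.pos = np.concatenate([base, base + G])
        else:
            self.pos = base

    def id_at(self, j: int) -> str:
        return self.ids[j % self.n]


class GenomeIndex:
    """Searchable promoter/terminator index of a genome annotation."""

    def __init__(self, genome: GenomeAnnotation, recognized: frozenset[str]):
        self.genome = genome
        self.G = genome.length
        self.circular = genome.circular
        self.max_read_through = max(
            (t.read_through_prob for t in genome.terminators()), default=0.0
        )
        self.prom: dict[str, _StrandFeatures] = {}
        self.term: dict[str, _StrandFeatures] = {}
        for strand in (FORWARD, REVERSE):
            pp = [(p.position, p.id) for p in genome.promoters()
                  if p.strand == strand and p.id in recognized]
            tt = [(t.position, t.id) for t in genome.terminators() if t.strand == strand]
            self.prom[strand] = _StrandFeatures([x for x, _ in pp], [i for _, i in pp],
                                                self.G, self.circular)
            self.term[strand] = _StrandFeatures([x for x, _ in tt], [i for _, i in tt],
                                                self.G, self.circular)


# ---------------------------------------------------------------------------
# vectorized classification core (absolute termination, read_through_prob = 0)


def _classify_sense_forward(idx: GenomeIndex, s: np.ndarray, e: np.ndarray,
                            mode: VectorMode) -> tuple[np.ndarray, np.ndarray]:
    """Classify placements whose sense strand is '+' (orientation A).

    Returns (fires, firing_promoter_index) where the index is into the
    sorted '+' recognized-promoter array modulo n, or -1.
    """
    prom, term = idx.prom[FORWARD], idx.term[FORWARD]
    if prom.pos.size:
        ip = np.searchsorted(prom.pos, e, side="left") - 1   # last promoter < e
        has_p = ip >= 0
        pstar = np.where(has_p, prom.pos[np.maximum(ip, 0)], np.int64(-1))
    else:
        ip = np.full(s.size, -1, dtype=np.int64)
        has_p = np.zeros(s.size, dtype=bool)
        pstar = np.full(s.size, -1, dtype=np.int64)
    if term.pos.size:
        it = np.searchsorted(term.pos, e, side="left") - 1   # last terminator < e
        tlast = np.where(it >= 0, term.pos[np.maximum(it, 0)], np.int64(-1))
        n_term = (np.searchsorted(term.pos, e, side="left")
                  - np.searchsorted(term.pos, s, side="left"))
    else:
        tlast = np.full(s.size, -1, dtype=np.int64)
        n_term = np.zeros(s.size, dtype=np.int64)
    promoterless_fires = has_p & (pstar >= s) & (pstar > tlast)
    if mode.kind == "promoterless":
        fires = promoterless_fires
        pidx = np.where(fires, ip, -1)
    else:
        no_term = n_term == 0
        fires = no_term.copy()
        if mode.internal_rescue:
            fires |= promoterless_fires
        # a no-terminator placement is read-through; only rescued placements
        # carry a promoter attribution
        pidx = np.where(fires & ~no_term & promoterless_fires, ip, -1)
    return fires, pidx


def _classify_sense_reverse(idx: GenomeIndex, s: np.ndarray, e: np.ndarray,
                            mode: VectorMode) -> tuple[np.ndarray, np.ndarray]:
    """Classify placements whose sense strand is '-' (orientation B).

    The reporter sits at the low-coordinate end; transcription runs toward
    decreasing coordinates, so the eligible promoter is the first recognized
    '-' promoter at or after s, and a '-' terminator strictly between s and
    that promoter blocks it.
    """
    prom, term = idx.prom[REVERSE], idx.term[REVERSE]
    big = np.iinfo(np.int64).max
    if prom.pos.size:
        jp = np.searchsorted(prom.pos, s, side="left")       # first promoter >= s
        has_p = jp < prom.pos.size
        pstar = np.where(has_p, prom.pos[np.minimum(jp, prom.pos.size - 1)], big)
    else:
        jp = np.zeros(s.size, dtype=np.int64)
        has_p = np.zeros(s.size, dtype=bool)
        pstar = np.full(s.size, big, dtype=np.int64)
    if term.pos.size:
        jt = np.searchsorted(term.pos, s, side="right")      # first terminator > s
        tfirst = np.where(jt < term.pos.size,
                          term.pos[np.minimum(jt, term.pos.size - 1)], big)
        n_term = (np.searchsorted(term.pos, e, side="left")
                  - np.searchsorted(term.pos, s, side="left"))
    else:
        tfirst = np.full(s.size, big, dtype=np.int64)
        n_term = np.zeros(s.size, dtype=np.int64)
    promoterless_fires = has_p & (pstar < e) & (pstar < tfirst)
    if mode.kind == "promoterless":
        fires = promoterless_fires
        pidx = np.where(fires, jp, -1)
    else:
        no_term = n_term == 0
        fires = no_term.copy()
        if mode.internal_rescue:
            fires |= promoterless_fires
        pidx = np.where(fires & ~no_term & promoterless_fires, jp, -1)
    return fires, pidx


def _classify_batch(idx: GenomeIndex, starts: np.ndarray, lengths: np.ndarray,
                    orient_a: np.ndarray, mode: VectorMode
                    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Classify a batch of inserts; requires all read_through_prob == 0.

    Returns (fires, promoter_index, is_orientation_A); promoter_index is a
    per-strand sorted-array index (mod n) or -1 when no promoter fired.
    """
    if idx.max_read_through > 0:
        raise ValueError("vectorized classification requires read_through_prob == 0; "
                         "use classify_insert with an rng for leaky terminators")
    e = starts + lengths
    if not idx.circular and np.any(e > idx.G):
        raise ValueError("insert extends past the end of a linear genome")
    fires = np.zeros(starts.size, dtype=bool)
    pidx = np.full(starts.size, -1, dtype=np.int64)
    a = orient_a
    if np.any(a):
        fires[a], pidx[a] = _classify_sense_forward(idx, starts[a], e[a], mode)
    b = ~a
    if np.any(b):
        fires[b], pidx[b] = _classify_sense_reverse(idx, starts[b], e[b], mode)
    return fires, pidx, orient_a


# ---------------------------------------------------------------------------
# public operations


def shear(genome: GenomeAnnotation, length_model: FragmentLengthModel, n: int,
          seed: int) -> list[Insert]:
    """Randomly shear ``n`` inserts: uniform start, Bernoulli(0.5) orientation.

    On circular genomes every start is valid and fragments may wrap the
    origin; on linear genomes each start is uniform on [0, length - L].
    Deterministic given the seed.
    """
    starts, lengths, orient_a = _shear_arrays(genome, length_model, n, seed)
    return [Insert(int(s), int(l), ORIENT_A if oa else ORIENT_B)
            for s, l, oa in zip(starts, lengths, orient_a)]


def _shear_arrays(genome: GenomeAnnotation, length_model: FragmentLengthModel,
                  n: int, seed: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    if n <= 0:
        raise ValueError("n must be positive")
    if genome.length <= length_model.max_bp:
        raise ValueError(
            f"genome length {genome.length} must exceed the maximum fragment "
            f"length {length_model.max_bp}"
        )
    rng = np.random.default_rng(seed)
    lengths = length_model.sample(rng, n)
    if genome.circular:
        starts = rng.integers(0, genome.length, size=n, dtype=np.int64)
    else:
        starts = (rng.random(n) * (genome.length - lengths + 1)).astype(np.int64)
    orient_a = rng.random(n) < 0.5
    return starts, lengths, orient_a


def classify_insert(insert: Insert, genome: GenomeAnnotation, mode: VectorMode,
                    sigma: SigmaRecognitionModel,
                    rng: np.random.Generator | None = None) -> ClassificationResult:
    """Classify a single insert, reporting the cause of any reporter signal.

    With leaky terminators (read_through_prob > 0) each terminator inside the
    insert is sampled once from ``rng``: it blocks with probability
    1 - read_through_prob.  Ties among several firing promoters resolve to
    the reporter-proximal-most one.
    """
    G = genome.length
    if insert.end > G and not genome.circular:
        raise ValueError("insert wraps on a linear genome")
    if insert.length > G:
        raise ValueError("insert longer than the genome")
    sense = FORWARD if insert.orientation == ORIENT_A else REVERSE
    recognized = sigma.resolve(genome)

    def unwrap(p: int) -> int:
        # map a feature position into the insert's unwrapped window [s, e)
        return p + G if genome.circular and p < insert.start and p + G < insert.end else p

    s, e = insert.start, insert.end
    proms = sorted(
        ((unwrap(p.position), p.id) for p in genome.promoters()
         if p.strand == sense and s <= unwrap(p.position) < e),
    )
    terms = sorted(
        ((unwrap(t.position), t.id, t.read_through_prob) for t in genome.terminators()
         if t.strand == sense and s <= unwrap(t.position) < e),
    )
    # materialize leaky-terminator outcomes: keep only the ones that block
    blocking = []
    for pos, tid, rho in terms:
        if rho > 0.0:
            if rng is None:
                raise ValueError("read_through_prob > 0 requires an rng")
            if rng.random() < rho:
                continue  # read through
        blocking.append((pos, tid))

    if sense == FORWARD:
        reporter_high = True  # reporter at the e end
    else:
        reporter_high = False

    def fires_from_promoter() -> tuple[str | None, str | None]:
        """(firing promoter id, blocking terminator id) for the trap rule."""
        cands = [(pos, pid) for pos, pid in proms if pid in recognized]
        if not cands:
            return None, None
        if reporter_high:
            pos, pid = max(cands)
            blockers = [t for t in blocking if t[0] > pos]
            return (pid, None) if not blockers else (None, min(blockers)[1])
        pos, pid = min(cands)
        blockers = [t for t in blocking if t[0] < pos]
        return (pid, None) if not blockers else (None, max(blockers)[1])

    if mode.kind == "promoterless":
        pid, blocker = fires_from_promoter()
        if pid is not None:
            return ClassificationResult(True, "promoter_fired", cause_id=pid)
        return ClassificationResult(False, "none", blocking_terminator=blocker)

    # upstream_promoter: vector promoter enters at the reporter-distal end
    if not blocking:
        return ClassificationResult(True, "read_through")
    first_hit = min(blocking) if reporter_high else max(blocking)
    if mode.internal_rescue:
        pid, _ = fires_from_promoter()
        if pid is not None:
            return ClassificationResult(True, "promoter_fired", cause_id=pid)
    return ClassificationResult(False, "none", blocking_terminator=first_hit[1])


def gfp_fraction_exact(genome: GenomeAnnotation, mode: VectorMode,
                       sigma: SigmaRecognitionModel, L: int) -> float:
    """Exact reporter-positive fraction over every placement at fixed length L.

    Enumerates every start (all of [0, G) on circular genomes; [0, G - L] on
    linear) in both orientations and returns positives / total.  Requires
    absolute termination (read_through_prob = 0 everywhere).
    """
    frac, _ = _exact_enumeration(genome, mode, sigma, L)
    return frac


def promoter_firing_weights(genome: GenomeAnnotation, mode: VectorMode, L: int,
                            sigma: SigmaRecognitionModel | None = None) -> dict[str, int]:
    """Per-promoter count of placements it fires, from exact enumeration.

    The weights quantify how much of the positive fraction each promoter
    carries; they feed the effective-promoter-count term of
    :func:`recognized_fraction_ci`.
    """
    _, weights = _exact_enumeration(genome, mode, sigma or SigmaRecognitionModel("all"), L)
    return weights


def _exact_enumeration(genome: GenomeAnnotation, mode: VectorMode,
                       sigma: SigmaRecognitionModel, L: int
                       ) -> tuple[float, dict[str, int]]:
    if L > genome.length:
        raise ValueError("fragment length exceeds genome length")
    if L < 1:
        raise ValueError("fragment length must be >= 1")
    recognized = sigma.resolve(genome)
    idx = GenomeIndex(genome, recognized)
    if idx.max_read_through > 0:
        raise ValueError("exact enumeration requires read_through_prob == 0")
    if genome.circular:
        starts = np.arange(genome.length, dtype=np.int64)
    else:
        starts = np.arange(genome.length - L + 1, dtype=np.int64)
    lengths = np.full_like(starts, L)
    total = 0
    positive = 0
    weights: dict[str, int] = {}
    for orient_a in (True, False):
        oa = np.full(starts.size, orient_a)
        fires, pidx, _ = _classify_batch(idx, starts, lengths, oa, mode)
        positive += int(fires.sum())
        total += starts.size
        feats = idx.prom[FORWARD if orient_a else REVERSE]
        fired = pidx[pidx >= 0]
        if fired.size and feats.n:
            counts = np.bincount(fired % feats.n, minlength=feats.n)
            for j, c in enumerate(counts):
                if c:
                    weights[feats.ids[j]] = weights.get(feats.ids[j], 0) + int(c)
    return positive / total, weights


@dataclass(frozen=True)
class GfpEstimate:
    """Monte-Carlo estimate of the reporter-positive fraction."""

    fraction: float
    ci_low: float
    ci_high: float
    n: int
    n_positive: int
    cause_counts: dict = field(default_factory=dict)

    @property
    def se(self) -> float:
        p = self.fraction
        return math.sqrt(p * (1 - p) / self.n)


def estimate_gfp_fraction_mc(genome: GenomeAnnotation, mode: VectorMode,
                             sigma: SigmaRecognitionModel,
                             length_model: FragmentLengthModel, n: int, seed: int,
                             ci_method: str = "normal") -> GfpEstimate:
    """Monte-Carlo reporter-positive fraction over ``n`` sheared inserts.

    The 95% CI uses the normal approximation by default (``ci_method`` may be
    ``"wilson"``).  Deterministic given the seed.
    """
    starts, lengths, orient_a = _shear_arrays(genome, length_model, n, seed)
    recognized = sigma.resolve(genome)
    idx = GenomeIndex(genome, recognized)
    fires, pidx, _ = _classify_batch(idx, starts, lengths, orient_a, mode)
    k = int(fires.sum())
    lo, hi = proportion_confint(k, n, alpha=0.05, method=ci_method)
    n_promoter = int((pidx >= 0).sum())
    causes = {
        "promoter_fired": n_promoter,
        "read_through": k - n_promoter if mode.kind == "upstream_promoter" else 0,
        "none": n - k,
    }
    return GfpEstimate(fraction=k / n, ci_low=float(lo), ci_high=float(hi),
                       n=n, n_positive=k, cause_counts=causes)


@dataclass(frozen=True)
class RecognizedFraction:
    """Observed/predicted-maximum ratio estimating the recognized promoter fraction."""

    estimate: float
    clipped: bool


def estimate_recognized_fraction(observed_fraction: float,
                                 predicted_max_fraction: float) -> RecognizedFraction:
    """Recognized promoter fraction as observed / predicted-maximum.

    ``predicted_max_fraction`` is the positive fraction under full
    recognition; the ratio is clipped into [0, 1] with a flag.
    """
    if predicted_max_fraction <= 0:
        raise ValueError("predicted_max_fraction must be positive")
    if observed_fraction < 0:
        raise ValueError("observed_fraction must be non-negative")
    raw = observed_fraction / predicted_max_fraction
    clipped = not (0.0 <= raw <= 1.0)
    return RecognizedFraction(estimate=min(max(raw, 0.0), 1.0), clipped=clipped)


def recognized_fraction_ci(n_positive: int, n: int, predicted_max: float,
                           firing_weights: Iterable[int] | None = None,
                           alpha: float = 0.05) -> tuple[float, float]:
    """Conservative CI for the recovered recognized-promoter fraction.

    Two binomial sources move the estimate across seeded runs: sampling of
    inserts (Wilson interval on the observed fraction, scaled by the
    predicted maximum) and the Bernoulli recognition draw over promoters
    (variance p(1-p) / n_eff with n_eff the effective promoter count
    (sum w)^2 / sum w^2 from exact firing weights).  The two half-widths are
    each taken at alpha/2 and summed, giving coverage of at least 1 - alpha.
    """
    if predicted_max <= 0:
        raise ValueError("predicted_max must be positive")
    from scipy.stats import norm

    lo_obs, hi_obs = proportion_confint(n_positive, n, alpha=alpha / 2, method="wilson")
    lo, hi = lo_obs / predicted_max, hi_obs / predicted_max
    p_hat = min(max((n_positive / n) / predicted_max, 0.0), 1.0)
    if firing_weights is not None:
        w = np.asarray(list(firing_weights), dtype=float)
        if w.size and w.sum() > 0:
            n_eff = w.sum() ** 2 / (w ** 2).sum()
            half = norm.ppf(1 - alpha / 4) * math.sqrt(p_hat * (1 - p_hat) / n_eff)
            lo, hi = lo - half, hi + half
    return max(lo, 0.0), min(hi, 1.0)
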