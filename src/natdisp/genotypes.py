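"""Individual identification from multilocus microsatellite genotypes.

Implements the two-step identity screen used in genetic mark-recapture of
territorial raptors: a chick and a breeding adult are accepted as the same
individual only on a full genotype match plus concordant molecular sex.
Samples fully typed at the 9-locus primary panel are matched in a first
screen; samples typed at 7 or 8 primary loci that show no mismatch are
re-screened after extending both members of the pair to 8 additional loci,
and accepted only on a full match across all co-typed loci of the 17.

Reliability of the panels is quantified by the probability of identity,
both for unrelated individuals (PI) and corrected for the presence of full
siblings (PI_sib), multiplied across loci.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Optional, Sequence

import numpy as np

Sex = str  # "male" | "female" | "unknown"

PRIMARY_LOCI = (
    "Aa02", "Aa35", "Aa36", "Aa39", "Aa43",
    "Hal04", "Hal10", "IEAAAG09", "IEAAAG11",
)
EXTENDED_LOCI = (
    "Aa26", "Aa41", "Aa49", "Aa53", "Aa57",
    "AQJ10", "AQJ22", "AQJ120",
)


@dataclass(frozen=True)
class LocusPanel:
    """Named primary (9) and extended (8) microsatellite locus sets."""

    primary_loci: tuple = PRIMARY_LOCI
    extended_loci: tuple = EXTENDED_LOCI

    def __post_init__(self):
        if len(self.primary_loci) != 9 or len(self.extended_loci) != 8:
            raise ValueError("panel must have 9 primary and 8 extended loci")
        if set(self.primary_loci) & set(self.extended_loci):
            raise ValueError("primary and extended locus names must be disjoint")

    @property
    def all_loci(self) -> tuple:
        return self.primary_loci + self.extended_loci


@dataclass
class MultilocusGenotype:
    """Diploid allele calls over named loci, with a molecular sex call.

    ``calls`` maps locus name to an unordered allele pair (two ints) or is
    simply absent/None for an untyped locus. Allele order is normalised on
    construction so (a, b) and (b, a) compare equal.
    """

    sample_id: str
    calls: dict = field(default_factory=dict)
    sex: Sex = "unknown"

    def __post_init__(self):
        norm = {}
        for locus, pair in self.calls.items():
            if pair is None:
                continue
            a, b = pair
            if a is None or b is None:
                continue  # a locus is fully typed or missing, never half
            norm[locus] = (int(a), int(b)) if a <= b else (int(b), int(a))
        self.calls = norm

    def typed_loci(self, loci: Iterable[str]) -> list:
        return [l for l in loci if l in self.calls]


@dataclass
class MatchResult:
    chick_id: str
    adult_id: str
    n_compared_loci: int
    screen: Optional[str]  # "first" | "second" | None if never a candidate
    accepted: bool
    reject_reason: Optional[str]  # locus_mismatch | sex_mismatch | insufficient_loci | sex_unknown
    conflict: bool = False


def compare_genotypes(a: MultilocusGenotype, b: MultilocusGenotype,
                      loci: Sequence[str]) -> tuple:
    """Count co-typed loci and mismatches between two genotypes.

    A locus counts as co-typed when both samples carry a call there; a
    mismatch is an unequal unordered allele pair. Symmetric in (a, b).
    """
    known = set(a.calls) | set(b.calls)
    for locus in loci:
        if locus not in known and locus not in PRIMARY_LOCI + EXTENDED_LOCI:
            raise KeyError(f"unknown locus: {locus}")
    n_cotyped = 0
    n_mismatch = 0
    for locus in loci:
        pa = a.calls.get(locus)
        pb = b.calls.get(locus)
        if pa is None or pb is None:
            continue
        n_cotyped += 1
        if pa != pb:
            n_mismatch += 1
    return n_cotyped, n_mismatch


def _encode(samples: Sequence[MultilocusGenotype], loci: Sequence[str]) -> np.ndarray:
    """Pack genotypes into an (n, n_loci, 2) int array; missing = -1."""
    arr = np.full((len(samples), len(loci), 2), -1, dtype=np.int32)
    index = {l: j for j, l in enumerate(loci)}
    for i, s in enumerate(samples):
        for locus, (a, b) in s.calls.items():
            j = index.get(locus)
            if j is not None:
                arr[i, j, 0] = a
                arr[i, j, 1] = b
    return arr


def two_step_identify(chicks: Sequence[MultilocusGenotype],
                      adults: Sequence[MultilocusGenotype],
                      panel: LocusPanel = LocusPanel(),
                      extend: Optional[Callable[[str], Mapping]] = None,
                      keep_rejected: bool = True) -> list:
    """Two-step genotype matching of chicks against breeding adults.

    Screen 1 accepts pairs fully typed at all 9 primary loci with zero
    mismatches and concordant known sex. Screen 2 considers pairs with 7
    or 8 co-typed primary loci, zero mismatches and concordant sex: both
    samples are extended to the 8 additional loci (via the ``extend``
    callback if their calls are absent — the in-silico analogue of
    re-genotyping) and accepted only if no mismatch occurs on any co-typed
    locus of the 17.

    A chick accepted against two different adults (or an adult against two
    chicks) is a conflict: all involved matches are reported unaccepted
    with ``conflict=True`` pending review.

    With ``keep_rejected=False`` only accepted/conflicted results are
    returned (the full rejection census can be large).
    """
    prim = panel.primary_loci
    A = _encode(adults, prim)
    sex_a = np.array([s.sex for s in adults])
    results: list = []
    accepted: list = []

    for chick in chicks:
        c = _encode([chick], prim)[0]
        cot = (A[:, :, 0] >= 0) & (c[:, 0] >= 0)[None, :]
        mism = cot & ((A[:, :, 0] != c[None, :, 0]) | (A[:, :, 1] != c[None, :, 1]))
        n_cot = cot.sum(axis=1)
        n_mis = mism.sum(axis=1)

        for i, adult in enumerate(adults):
            res = _screen_pair(chick, adult, int(n_cot[i]), int(n_mis[i]),
                               panel, extend)
            if res.accepted:
                accepted.append(res)
                results.append(res)
            elif keep_rejected:
                results.append(res)

    _flag_conflicts(accepted, {c.sample_id: c for c in chicks},
                    {a.sample_id: a for a in adults}, panel)
    return results


def _screen_pair(chick, adult, n_cot, n_mis, panel, extend) -> MatchResult:
    if n_cot < 7:
        return MatchResult(chick.sample_id, adult.sample_id, n_cot, None,
                           False, "insufficient_loci")
    if n_mis > 0:
        screen = "first" if n_cot == 9 else "second"
        return MatchResult(chick.sample_id, adult.sample_id, n_cot, screen,
                           False, "locus_mismatch")
    # zero mismatches on >= 7 co-typed primary loci: sex gate
    if chick.sex == "unknown" or adult.sex == "unknown":
        screen = "first" if n_cot == 9 else "second"
        return MatchResult(chick.sample_id, adult.sample_id, n_cot, screen,
                           False, "sex_unknown")
    if chick.sex != adult.sex:
        screen = "first" if n_cot == 9 else "second"
        return MatchResult(chick.sample_id, adult.sample_id, n_cot, screen,
                           False, "sex_mismatch")
    if n_cot == 9:
        return MatchResult(chick.sample_id, adult.sample_id, 9, "first",
                           True, None)
    # second screen: extend both members to the full 17-locus panel
    for sample in (chick, adult):
        missing_ext = [l for l in panel.extended_loci if l not in sample.calls]
        if missing_ext and extend is not None:
            extra = extend(sample.sample_id)
            if extra:
                merged = dict(sample.calls)
                for locus in missing_ext:
                    if locus in extra and extra[locus] is not None:
                        a, b = extra[locus]
                        merged[locus] = (a, b) if a <= b else (b, a)
                sample.calls = merged
    n17, m17 = compare_genotypes(chick, adult, panel.all_loci)
    if m17 > 0:
        return MatchResult(chick.sample_id, adult.sample_id, n17, "second",
                           False, "locus_mismatch")
    return MatchResult(chick.sample_id, adult.sample_id, n17, "second",
                       True, None)


def _flag_conflicts(accepted: list, chicks: dict, adults: dict,
                    panel: LocusPanel) -> None:
    """Surface one-to-many conflicts, never silently resolving them.

    An adult sample accepted against two different chicks is always a
    conflict (distinct marked chicks are distinct birds). A chick
    accepted against several adult samples is only a conflict when some
    pair of those samples cannot itself be one individual (a mismatch on
    co-typed loci, or discordant known sex) — repeated sampling of the
    same breeding bird across years is the expected case.
    """
    by_chick: dict = {}
    by_adult: dict = {}
    for r in accepted:
        by_chick.setdefault(r.chick_id, []).append(r)
        by_adult.setdefault(r.adult_id, []).append(r)
    for group in by_adult.values():
        if len(group) > 1:
            for r in group:
                r.accepted = False
                r.conflict = True
    for group in by_chick.values():
        if len(group) < 2:
            continue
        samples = [adults[r.adult_id] for r in group]
        compatible = True
        for i in range(len(samples)):
            for j in range(i + 1, len(samples)):
                a, b = samples[i], samples[j]
                _, mism = compare_genotypes(a, b, panel.all_loci)
                sexes = {a.sex, b.sex} - {"unknown"}
                if mism > 0 or len(sexes) > 1:
                    compatible = False
        if not compatible:
            for r in group:
                r.accepted = False
                r.conflict = True


# ---------------------------------------------------------------------------
# Probability of identity
# ---------------------------------------------------------------------------

def _check_freqs(freqs) -> np.ndarray:
    p = np.asarray(freqs, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("allele frequencies must be a non-empty 1-d vector")
    if np.any(p < 0):
        raise ValueError("allele frequencies must be non-negative")
    if abs(p.sum() - 1.0) > 1e-8:
        raise ValueError(f"allele frequencies must sum to 1 (got {p.sum()})")
    return p


def pi_locus(freqs) -> float:
    """Probability that two unrelated individuals share a genotype at a locus.

    Under Hardy-Weinberg: PI = 2 (sum p_i^2)^2 - sum p_i^4.
    """
    p = _check_freqs(freqs)
    s2 = float(np.sum(p ** 2))
    s4 = float(np.sum(p ** 4))
    return 2.0 * s2 ** 2 - s4


def pi_sib_locus(freqs) -> float:
    """Probability of identity at a locus for a pair of full siblings.

    PI_sib = 0.25 + 0.5 sum p_i^2 + 0.5 (sum p_i^2)^2 - 0.25 sum p_i^4.
    Always >= the unrelated-pair PI; the relevant bound in populations
    rich in siblings.
    """
    p = _check_freqs(freqs)
    s2 = float(np.sum(p ** 2))
    s4 = float(np.sum(p ** 4))
    return 0.25 + 0.5 * s2 + 0.5 * s2 ** 2 - 0.25 * s4


def multilocus_pi(per_locus_values: Sequence[float]) -> float:
    """Multilocus probability of identity: product of per-locus values."""
    vals = list(per_locus_values)
    if not vals:
        raise ValueError("empty locus set")
    return float(np.prod(vals))


def allele_frequencies(samples: Sequence[MultilocusGenotype],
                       loci: Sequence[str]) -> dict:
    """Empirical allele frequencies per locus from a reference sample.

    By convention the reference sample is the breeding-adult genotype set;
    any sample collection may be passed.
    """
    out = {}
    for locus in loci:
        counts: dict = {}
        for s in samples:
            pair = s.calls.get(locus)
            if pair is None:
                continue
            for allele in pair:
                counts[allele] = counts.get(allele, 0) + 1
        total = sum(counts.values())
        if total == 0:
            out[locus] = np.array([])
        else:
            out[locus] = np.array([c / total for c in counts.values()])
    return out
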