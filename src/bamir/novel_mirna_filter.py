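"""High-confidence filter for novel pre-miRNA hairpin candidates.

Genuine Drosha/Dicer processing leaves characteristic footprints in a small
RNA-seq read stack aligned to a candidate hairpin: a dominant mature arm
(here ≥30 perfectly matching reads) backed by a detectable star arm (≥10),
precise 5' ends (≥50% of arm reads sharing the modal 5' start), a 0–4 nt
3' overhang of the mature:star duplex, a single stem-loop with no internal
sub-hairpins, and a folding energy at or below −0.2 kcal/mol per
nucleotide.  A candidate passes only if every criterion holds.

All thresholds are inclusive as written and configurable through
:class:`FilterCriteria`.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

from bamir.io_formats import StructureRecord

logger = logging.getLogger(__name__)

ARM_ASSIGN_WINDOW = 3  # nt tolerance around an arm's annotated 5' end


class StructureError(ValueError):
    """Raised for malformed dot-bracket structures."""


@dataclass(frozen=True)
class HairpinCandidate:
    """A candidate precursor with structure, MFE and annotated arms.

    Arm intervals are 0-based half-open within the precursor; ``mature_arm``
    and ``star_arm`` must be disjoint and each at least 16 nt.
    """

    id: str
    sequence: str
    dot_bracket: str
    mfe_kcal_mol: float
    mature_arm: tuple[int, int]
    star_arm: tuple[int, int]

    def __post_init__(self) -> None:
        n = len(self.sequence)
        for name, (s, e) in (("mature_arm", self.mature_arm), ("star_arm", self.star_arm)):
            if not (0 <= s < e <= n):
                raise ValueError(f"{self.id!r}: {name} {s, e} outside precursor of length {n}")
            if e - s < 16:
                raise ValueError(f"{self.id!r}: {name} shorter than 16 nt")
        lo, hi = sorted([self.mature_arm, self.star_arm])
        if lo[1] > hi[0]:
            raise ValueError(f"{self.id!r}: mature and star arms overlap")

    @property
    def structure(self) -> StructureRecord:
        return StructureRecord(self.id, self.sequence, self.dot_bracket, self.mfe_kcal_mol)


@dataclass(frozen=True)
class AlignedRead:
    """A collapsed read alignment: precursor coordinates plus multiplicity."""

    start: int
    end: int
    mismatches: int
    count: int

    def __post_init__(self) -> None:
        if not 18 <= self.end - self.start <= 25:
            raise ValueError(f"read length {self.end - self.start} outside 18-25 nt")
        if self.mismatches < 0 or self.count < 1:
            raise ValueError("mismatches must be >= 0 and count >= 1")


@dataclass(frozen=True)
class FilterCriteria:
    mature_min_reads: int = 30
    star_min_reads: int = 10
    homogeneity_min: float = 0.5
    overhang_range: tuple[int, int] = (0, 4)
    mfe_per_nt_max: float = -0.2
    max_hairpin_loops: int = 1
    # which arm(s) the 5' homogeneity criterion is measured on
    homogeneity_arm: str = "mature"  # "mature" | "star" | "both"
    # denominator for homogeneity: all arm reads, or 0-mismatch reads only
    homogeneity_zero_mismatch_only: bool = False

    def __post_init__(self) -> None:
        if self.overhang_range[0] > self.overhang_range[1]:
            raise ValueError("empty overhang range")
        if self.homogeneity_arm not in ("mature", "star", "both"):
            raise ValueError(f"unknown homogeneity_arm {self.homogeneity_arm!r}")


@dataclass(frozen=True)
class CriterionResult:
    value: float
    passed: bool
    message: str = ""


@dataclass(frozen=True)
class FilterReport:
    """Per-criterion measured values and decisions for one candidate."""

    candidate_id: str
    criteria: dict[str, CriterionResult]
    overall_pass: bool

    CRITERION_NAMES = (
        "mature_support",
        "star_support",
        "homogeneity",
        "overhang",
        "mfe_per_nt",
        "hairpin_loops",
    )


def pair_table(dot_bracket: str) -> list[int]:
    """Partner index for each position (-1 if unpaired); errors if unbalanced."""
    partner = [-1] * len(dot_bracket)
    stack: list[int] = []
    for i, ch in enumerate(dot_bracket):
        if ch == "(":
            stack.append(i)
        elif ch == ")":
            if not stack:
                raise StructureError("unbalanced dot-bracket: unmatched ')'")
            j = stack.pop()
            partner[i], partner[j] = j, i
        elif ch != ".":
            raise StructureError(f"illegal structure character {ch!r}")
    if stack:
        raise StructureError("unbalanced dot-bracket: unmatched '('")
    return partner


_HAIRPIN_LOOP = re.compile(r"\(\.*\)")


def count_hairpin_loops(dot_bracket: str) -> int:
    """Number of hairpin loops: unpaired runs closed by a pair with nothing inside.

    A clean single stem-loop has exactly one; any bifurcation or internal
    sub-hairpin contributes additional loops.
    """
    pair_table(dot_bracket)  # validation only
    return len(_HAIRPIN_LOOP.findall(dot_bracket))


def assign_reads_to_arms(
    reads: list[AlignedRead], candidate: HairpinCandidate
) -> tuple[list[AlignedRead], list[AlignedRead], list[AlignedRead]]:
    """Partition reads by arm: a read joins an arm iff its 5' end lies within
    ±3 nt of that arm's annotated 5' end; everything else is unassigned.
    """
    n = len(candidate.sequence)
    mature, star, unassigned = [], [], []
    for read in reads:
        if read.start < 0 or read.end > n:
            raise ValueError(
                f"read [{read.start},{read.end}) outside precursor {candidate.id!r} (len {n})"
            )
        if abs(read.start - candidate.mature_arm[0]) <= ARM_ASSIGN_WINDOW:
            mature.append(read)
        elif abs(read.start - candidate.star_arm[0]) <= ARM_ASSIGN_WINDOW:
            star.append(read)
        else:
            unassigned.append(read)
    return mature, star, unassigned


def arm_support(arm_reads: list[AlignedRead]) -> int:
    """Multiplicity-weighted count of perfect (0-mismatch) reads on an arm."""
    return sum(r.count for r in arm_reads if r.mismatches == 0)


def five_prime_homogeneity(arm_reads: list[AlignedRead]) -> float:
    """Weighted fraction of arm reads sharing the modal 5' start position.

    All reads count regardless of mismatches; an empty arm yields 0.0
    (reported as a criterion failure by the caller).
    """
    if not arm_reads:
        return 0.0
    by_start: dict[int, int] = {}
    for r in arm_reads:
        by_start[r.start] = by_start.get(r.start, 0) + r.count
    total = sum(by_start.values())
    return max(by_start.values()) / total


def three_prime_overhang(candidate: HairpinCandidate) -> int | None:
    """Length of the 3'-arm 3' overhang of the mature:star duplex.

    Measured as the distance the 3'-arm strand's 3' terminus protrudes past
    the base paired with the 5'-arm strand's 5' terminus.  A recessed end
    gives a negative value.  If the 5'-arm 5' terminus is unpaired, the
    first paired position within the next 3 nt anchors the measurement
    (compensated by the shift); if none exists the overhang is undefined
    and ``None`` is returned.
    """
    partner = pair_table(candidate.dot_bracket)
    five_arm, three_arm = sorted([candidate.mature_arm, candidate.star_arm])
    p5 = five_arm[0]
    anchor = None
    for q in range(p5, p5 + ARM_ASSIGN_WINDOW + 1):
        if q < len(partner) and partner[q] >= 0:
            anchor = q
            break
    if anchor is None:
        return None
    # shift compensation: treat partner as if the terminus itself were paired
    paired_pos = partner[anchor] + (anchor - p5)
    three_terminus = three_arm[1] - 1
    return three_terminus - paired_pos


def mfe_per_nucleotide(mfe_kcal_mol: float, precursor_length: int) -> float:
    if precursor_length <= 0:
        raise ValueError("precursor length must be positive")
    return mfe_kcal_mol / precursor_length


def evaluate_candidate(
    candidate: HairpinCandidate,
    reads: list[AlignedRead],
    criteria: FilterCriteria | None = None,
) -> FilterReport:
    """Apply every filter criterion and report the measured values.

    ``overall_pass`` is the conjunction of the six per-criterion decisions.
    """
    crit = criteria or FilterCriteria()
    results: dict[str, CriterionResult] = {}

    mature, star, _ = assign_reads_to_arms(reads, candidate)
    m_support = arm_support(mature)
    s_support = arm_support(star)
    results["mature_support"] = CriterionResult(m_support, m_support >= crit.mature_min_reads)
    results["star_support"] = CriterionResult(s_support, s_support >= crit.star_min_reads)

    arms = {"mature": [mature], "star": [star], "both": [mature, star]}[crit.homogeneity_arm]
    homog_values = []
    for arm_reads in arms:
        if crit.homogeneity_zero_mismatch_only:
            arm_reads = [r for r in arm_reads if r.mismatches == 0]
        homog_values.append(five_prime_homogeneity(arm_reads))
    homogeneity = min(homog_values)
    results["homogeneity"] = CriterionResult(
        homogeneity,
        homogeneity >= crit.homogeneity_min and homogeneity > 0,
        "" if homogeneity > 0 else "no reads on arm",
    )

    try:
        overhang = three_prime_overhang(candidate)
    except StructureError as exc:
        overhang = None
        logger.warning("%s: %s", candidate.id, exc)
    if overhang is None:
        results["overhang"] = CriterionResult(
            float("nan"), False, "overhang undefined: 5'-arm terminus unpaired"
        )
    else:
        lo, hi = crit.overhang_range
        results["overhang"] = CriterionResult(overhang, lo <= overhang <= hi)

    mfe_nt = mfe_per_nucleotide(candidate.mfe_kcal_mol, len(candidate.sequence))
    results["mfe_per_nt"] = CriterionResult(mfe_nt, mfe_nt <= crit.mfe_per_nt_max)

    try:
        loops = count_hairpin_loops(candidate.dot_bracket)
        results["hairpin_loops"] = CriterionResult(loops, loops <= crit.max_hairpin_loops)
    except StructureError as exc:
        results["hairpin_loops"] = CriterionResult(float("nan"), False, str(exc))

    overall = all(r.passed for r in results.values())
    return FilterReport(candidate.id, results, overall)


def apply_filter(
    candidates: list[HairpinCandidate],
    reads_by_candidate: dict[str, list[AlignedRead]],
    criteria: FilterCriteria | None = None,
    exclude_ids: set[str] | None = None,
) -> tuple[list[FilterReport], list[HairpinCandidate]]:
    """Evaluate a batch of candidates; return all reports and the survivors.

    ``exclude_ids`` drops known annotated ncRNAs before evaluation (the
    hook that replaces a database cross-search).
    """
    exclude = exclude_ids or set()
    reports, retained = [], []
    for cand in candidates:
        if cand.id in exclude:
            logger.info("%s excluded via known-ncRNA list", cand.id)
            continue
        report = evaluate_candidate(cand, reads_by_candidate.get(cand.id, []), criteria)
        reports.append(report)
        if report.overall_pass:
            retained.append(cand)
    return reports, retained


def seed_family_match(
    novel_matures: list, reference_matures: list
) -> list[tuple[str, str]]:
    """Pair novel and reference mature miRNAs sharing the seed (nt 2-8).

    Accepts any records with ``id`` and ``sequence`` attributes of length
    ≥ 8 nt; a pair is reported iff positions 2-8 (1-based) are identical.
    """
    pairs = []
    for novel in novel_matures:
        if len(novel.sequence) < 8:
            continue
        seed = novel.sequence[1:8]
        for ref in reference_matures:
            if len(ref.sequence) >= 8 and ref.sequence[1:8] == seed:
                pairs.append((novel.id, ref.id))
    return pairs
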