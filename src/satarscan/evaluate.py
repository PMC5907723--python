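"""Scoring detected annotations against simulation ground truth."""

from __future__ import annotations

from dataclasses import dataclass, field

from .arrays import ElementArray
from .comparative import SiteCall
from .families import ElementOccurrence
from .simulate import TruthRecord


@dataclass
class RecoveryReport:
    n_truth: int
    n_detected: int
    n_matched: int
    precision: float | None
    recall: float
    flank_accuracy: float | None = None
    flank_n: int = 0
    array_pair_agreement: float | None = None
    site_confusion: dict[tuple[str, str], int] = field(default_factory=dict)
    matches: list[tuple[TruthRecord, ElementOccurrence]] = field(
        default_factory=list)

    @property
    def site_diagonal_mass(self) -> float | None:
        total = sum(self.site_confusion.values())
        if not total:
            return None
        diag = sum(v for (t, d), v in self.site_confusion.items() if t == d)
        return diag / total


def _overlap(a_start, a_end, b_start, b_end) -> int:
    return max(0, min(a_end, b_end) - max(a_start, b_start))


def match_occurrences(truth: list[TruthRecord],
                      detected: list[ElementOccurrence],
                      min_reciprocal_overlap: float = 0.5
                      ) -> list[tuple[TruthRecord, ElementOccurrence]]:
    """Greedy one-to-one matching by decreasing reciprocal overlap."""
    pairs = []
    for ti, t in enumerate(truth):
        for di, d in enumerate(detected):
            if t.scaffold_id != d.scaffold_id:
                continue
            ov = _overlap(t.start, t.end, d.start, d.end)
            if ov == 0:
                continue
            rec = min(ov / (t.end - t.start), ov / (d.end - d.start))
            if rec >= min_reciprocal_overlap:
                pairs.append((rec, ti, di))
    pairs.sort(key=lambda p: (-p[0], p[1], p[2]))
    used_t, used_d = set(), set()
    matches = []
    for rec, ti, di in pairs:
        if ti in used_t or di in used_d:
            continue
        used_t.add(ti)
        used_d.add(di)
        matches.append((truth[ti], detected[di]))
    return matches


_EXPECTED_FLANK = {"satellite": "microsatellite", "tsd": "tsd"}


def evaluate_recovery(truth: list[TruthRecord],
                      detected: list[ElementOccurrence],
                      arrays: list[ElementArray] | None = None,
                      site_calls: list[SiteCall] | None = None,
                      min_reciprocal_overlap: float = 0.5) -> RecoveryReport:
    """Precision/recall of detection plus per-category breakdowns.

    Flank-class accuracy is computed over matched, non-fused,
    non-nested copies (fusion deletes the very flank architecture being
    scored). Array recovery is a Rand-style pair agreement of truth
    vs. detected co-membership over matched copies. Site calls are
    tallied into a confusion matrix against the truth site state
    (occupied unless the copy was excised in assembly B).
    """
    scorable = [t for t in truth if not t.split_host]
    matches = match_occurrences(scorable, detected, min_reciprocal_overlap)
    n_matched = len(matches)
    precision = n_matched / len(detected) if detected else None
    recall = n_matched / len(scorable) if scorable else 0.0
    report = RecoveryReport(len(scorable), len(detected), n_matched,
                            precision, recall, matches=matches)

    flank_ok = flank_n = 0
    for t, d in matches:
        if t.fused or t.nested_in is not None:
            continue
        expected = _EXPECTED_FLANK.get(t.insertion_mode)
        got = d.flank.category if d.flank is not None else None
        if t.nested_in is not None:
            continue
        if expected is None or got is None:
            continue
        flank_n += 1
        flank_ok += int(got == expected)
    if flank_n:
        report.flank_accuracy = flank_ok / flank_n
        report.flank_n = flank_n

    if arrays is not None:
        detected_array = {}
        for ai, arr in enumerate(arrays):
            for m in arr.members:
                detected_array[id(m)] = ai
        in_truth_arr = [(t, d) for t, d in matches]
        agree = total = 0
        for i in range(len(in_truth_arr)):
            for j in range(i + 1, len(in_truth_arr)):
                ti, di = in_truth_arr[i]
                tj, dj = in_truth_arr[j]
                same_truth = (ti.array_id is not None
                              and ti.array_id == tj.array_id)
                same_det = (detected_array.get(id(di)) is not None
                            and detected_array.get(id(di)) ==
                            detected_array.get(id(dj))
                            and len(arrays[detected_array[id(di)]].members) >= 2)
                total += 1
                agree += int(same_truth == same_det)
        if total:
            report.array_pair_agreement = agree / total

    if site_calls is not None:
        truth_by_match = {id(d): t for t, d in matches}
        for call in site_calls:
            t = truth_by_match.get(id(call.occurrence))
            if t is None:
                continue
            expected = "empty_satellite" if t.excised_in_B else "occupied"
            report.site_confusion[(expected, call.status)] = \
                report.site_confusion.get((expected, call.status), 0) + 1
    return report
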