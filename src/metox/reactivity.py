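"""The S-aromatic reactivity rule and its benchmarks.

The rule: a methionine engaged in an S-aromatic motif is predicted to be of
low reactivity toward peroxide (oxidation-resistant); every other methionine
is predicted to be highly reactive. The in-vitro benchmark scores the rule
against per-protein low/high reactivity labels derived from published
oxidation kinetics; the positive class is "low reactivity", so sensitivity is
the fraction of low-reactivity methionines correctly flagged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

from .io_data import MetSite, ReactivityRecord
from .stats import ContingencyTable2x2
from .structure import MotifCall

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConfusionMatrix:
    """TP/TN/FP/FN with positive class = low reactivity (motif predicted)."""

    tp: int
    tn: int
    fp: int
    fn: int
    positive_class: str = "low reactivity"

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.total

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp)

    def to_contingency(self) -> ContingencyTable2x2:
        """Rows: reactivity low/high; columns: motif yes/no."""
        return ContingencyTable2x2(
            self.tp,
            self.fn,
            self.fp,
            self.tn,
            row_labels=("low", "high"),
            col_labels=("motif", "no-motif"),
        )


def predict_reactivity(call: MotifCall) -> str:
    """'low' when the methionine forms an S-aromatic motif, else 'high'."""
    return "low" if call.forms_motif else "high"


def median_split_labels(reactivities: Sequence[tuple[object, float]]) -> dict[object, str]:
    """Split a protein's methionines into low/high reactivity about the median.

    ``reactivities`` holds (methionine key, empirical reactivity) pairs.
    Below-median residues are "low", above-median "high"; residues exactly at
    the median join the group containing the residue whose reactivity is
    closest to the median.

    Residues at the median join the group of the non-tied residue closest to
    the median (equidistant -> low); when that assignment would leave one
    group empty — impossible under the benchmark's construction, which needs
    both reactivity classes inhabited — the tied residues join the empty
    group instead.
    """
    if len(reactivities) < 2:
        raise ValueError("need at least two methionines per protein")
    import statistics

    values = [v for _, v in reactivities]
    med = statistics.median(values)
    labels: dict[object, str] = {}
    ties = []
    for key, v in reactivities:
        if v < med:
            labels[key] = "low"
        elif v > med:
            labels[key] = "high"
        else:
            ties.append(key)
    if ties:
        off_median = [(key, v) for key, v in reactivities if v != med]
        if not off_median:
            raise ValueError("all reactivities identical; median split undefined")
        best = min(abs(v - med) for _, v in off_median)
        candidates = {("low" if v < med else "high") for _, v in off_median if abs(v - med) == best}
        tie_group = "low" if "low" in candidates else "high"
        n_low = sum(1 for g in labels.values() if g == "low")
        n_high = sum(1 for g in labels.values() if g == "high")
        if tie_group == "high" and n_low == 0:
            tie_group = "low"
        elif tie_group == "low" and n_high == 0:
            tie_group = "high"
        for key in ties:
            labels[key] = tie_group
    return labels


def benchmark_confusion(
    records: Sequence[ReactivityRecord],
    calls: Mapping[tuple[str, int], MotifCall],
) -> ConfusionMatrix:
    """Score the motif rule against empirical low/high labels.

    ``calls`` is keyed by (pdb id, *sequence* methionine position) — author
    numbering must already have been translated through a ResidueMap. A record
    without a call is an error: silently assigning unresolved methionines
    would inflate the benchmark.
    """
    tp = tn = fp = fn = 0
    missing = [r for r in records if (r.pdb_id, r.met_pos) not in calls]
    if missing:
        raise KeyError(
            "no motif call for: "
            + ", ".join(f"{r.pdb_id}:{r.met_pos}" for r in missing)
        )
    for r in records:
        predicted = predict_reactivity(calls[(r.pdb_id, r.met_pos)])
        if r.reactivity_class == "low":
            if predicted == "low":
                tp += 1
            else:
                fn += 1
        else:
            if predicted == "high":
                tn += 1
            else:
                fp += 1
    return ConfusionMatrix(tp=tp, tn=tn, fp=fp, fn=fn)


def confusion_from_counts(counts) -> ConfusionMatrix:
    """Aggregate a per-protein tp/tn/fp/fn table (DataFrame) into one matrix."""
    return ConfusionMatrix(
        tp=int(counts["tp"].sum()),
        tn=int(counts["tn"].sum()),
        fp=int(counts["fp"].sum()),
        fn=int(counts["fn"].sum()),
    )


def oxidation_contingency(
    sites: Sequence[MetSite],
    calls: Mapping[tuple[str, int], MotifCall],
) -> ContingencyTable2x2:
    """2x2 table of in-vivo oxidation status against motif status.

    ``sites`` carry (protein_id, pos, oxidized); ``calls`` must be keyed by
    the same (protein_id, pos). Sites without a call are dropped and logged
    (unresolved methionines).
    """
    a = b = c = d = 0
    n_dropped = 0
    for site in sites:
        call = calls.get((site.protein_id, site.pos))
        if call is None:
            n_dropped += 1
            continue
        if site.oxidized and call.forms_motif:
            a += 1
        elif site.oxidized:
            b += 1
        elif call.forms_motif:
            c += 1
        else:
            d += 1
    if n_dropped:
        logger.info("oxidation_contingency: dropped %d sites without calls", n_dropped)
    return ContingencyTable2x2(
        a, b, c, d, row_labels=("oxidized", "not-oxidized"), col_labels=("motif", "no-motif")
    )
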