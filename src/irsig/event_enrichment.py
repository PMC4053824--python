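"""Alternative-splicing event classification and permutation enrichment.

Exons (distinct per-gene exon intervals over all transcripts) are assigned
one of six event classes from the annotation alone:

- CE   cassette exon: present in some isoforms, skipped (flanks joined by a
       junction spanning it) in others;
- MXE  mutually exclusive exons: a disjoint exon pair where isoforms carry
       exactly one of the two, each skipped over in the other's isoform;
- IR   intron retention: an isoform's single exon spans the exon plus an
       adjacent intron of another isoform (both the split and the merged
       exon are IR);
- A3SS / A5SS: overlapping exons of different isoforms sharing the donor-
       side (resp. acceptor-side) boundary while the other boundary moves;
- CNE  constitutive exon: anything else, including all exons of
       single-transcript genes.

When several definitions match, one primary label is kept with priority
MXE > CE > IR > A3SS > A5SS.

The enrichment of an exon selection (e.g. exons downstream of
high-retention introns) for each class is assessed by drawing equally
sized random exon sets without replacement from the universe; the
one-sided permutation p is (1 + #resamples at least as extreme) /
(resamples + 1), tested "greater" for CE, MXE, IR, A3SS and A5SS and
"less" for CNE.  With 1,000 resamples the attainable floor is 1/1001,
displayed as 0.001.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotation_model import GeneModelSet
from .ir_metrics import SSRatioRecord

EVENT_TYPES = ["CNE", "CE", "MXE", "IR", "A3SS", "A5SS"]
_PRIORITY = ["MXE", "CE", "IR", "A3SS", "A5SS"]
DEFAULT_RESAMPLES = 1000
DEFAULT_SELECT_THRESHOLD = 0.1

# direction of the one-sided alternative per event type
DIRECTIONS = {"CNE": "less", "CE": "greater", "MXE": "greater",
              "IR": "greater", "A3SS": "greater", "A5SS": "greater"}


def exon_event_id(gene_id: str, start: int, end: int) -> str:
    return f"{gene_id}:{start}-{end}"


def classify_events(models: GeneModelSet) -> dict[str, str]:
    """Assign each distinct exon of each gene a single event class."""
    labels: dict[str, str] = {}
    for gene in models:
        tx_exons = [tuple(t.exons) for t in gene.transcripts]
        exon_set = sorted({e for exons in tx_exons for e in exons})
        junctions = [
            {(exons[i][1], exons[i + 1][0]) for i in range(len(exons) - 1)}
            for exons in tx_exons
        ]
        matches: dict[tuple[int, int], set[str]] = {e: set() for e in exon_set}

        def skipped_in(exon, ti):
            """True if transcript ti lacks the exon but joins across it."""
            if exon in tx_exons[ti]:
                return False
            return any(d <= exon[0] and a >= exon[1] for d, a in junctions[ti])

        for e in exon_set:
            present = [ti for ti, exons in enumerate(tx_exons) if e in exons]
            if not present:
                continue
            # CE: skipped with flanks joined in some other isoform
            if any(skipped_in(e, ti) for ti in range(len(tx_exons))):
                matches[e].add("CE")
            # IR (merged side): e spans another isoform's junction entirely
            for jj in junctions:
                if any(e[0] < d and a < e[1] for d, a in jj):
                    matches[e].add("IR")
            # IR (split side): another isoform has an exon engulfing e plus
            # an adjacent intron of one of e's isoforms
            for ti in present:
                exons = tx_exons[ti]
                pos = exons.index(e)
                adj = []
                if pos > 0:
                    adj.append((exons[pos - 1][1], e[0]))
                if pos < len(exons) - 1:
                    adj.append((e[1], exons[pos + 1][0]))
                for d, a in adj:
                    for tj, other in enumerate(tx_exons):
                        if tj == ti:
                            continue
                        if any(g[0] < d and g[1] > a for g in other):
                            matches[e].add("IR")
            # boundary shifts among overlapping exons of other isoforms
            for f in exon_set:
                if f == e or f[1] <= e[0] or f[0] >= e[1]:
                    continue
                same_start, same_end = f[0] == e[0], f[1] == e[1]
                if same_start == same_end:
                    continue  # identical or both boundaries moved
                # on +: start is the acceptor side, end the donor side
                if gene.strand == "-":
                    acceptor_moved, donor_moved = not same_end, not same_start
                else:
                    acceptor_moved, donor_moved = not same_start, not same_end
                matches[e].add("A3SS" if acceptor_moved else "A5SS")

        # MXE: disjoint CE-like pairs never co-occurring, each skipped over
        # in an isoform carrying the other
        ce_like = [e for e in exon_set if "CE" in matches[e]]
        for i, e in enumerate(ce_like):
            for f in ce_like[i + 1:]:
                if not (e[1] <= f[0] or f[1] <= e[0]):
                    continue
                together = any(e in exons and f in exons for exons in tx_exons)
                if together:
                    continue
                e_only = [ti for ti, exons in enumerate(tx_exons)
                          if e in exons and skipped_in(f, ti)]
                f_only = [ti for ti, exons in enumerate(tx_exons)
                          if f in exons and skipped_in(e, ti)]
                if e_only and f_only:
                    matches[e].add("MXE")
                    matches[f].add("MXE")

        for e in exon_set:
            label = "CNE"
            for cand in _PRIORITY:
                if cand in matches[e]:
                    label = cand
                    break
            labels[exon_event_id(gene.id, *e)] = label
    return labels


def select_high_ir_exons(ssratios: list[SSRatioRecord],
                         exon_of_intron: dict[str, str],
                         condition: str,
                         threshold: float = DEFAULT_SELECT_THRESHOLD) -> set[str]:
    """Exons whose upstream intron has 3'SS ratio >= threshold in ``condition``.

    ``exon_of_intron`` maps intron feature id to the universe exon id of the
    transcription-downstream exon.
    """
    selected: set[str] = set()
    for rec in ssratios:
        ratio = rec.ratio_3ss.get(condition, math.nan)
        if math.isnan(ratio) or ratio < threshold:
            continue
        exon = exon_of_intron.get(rec.intron_id)
        if exon is not None:
            selected.add(exon)
    return selected


@dataclass
class EnrichmentReport:
    table: pd.DataFrame  # per event type: counts, mean background, p, direction
    resamples: int
    seed: int

    def p_value(self, event_type: str) -> float:
        return float(self.table.loc[event_type, "p_value"])


def permutation_enrichment(selected: set[str],
                           universe: list[str],
                           labels: dict[str, str],
                           resamples: int = DEFAULT_RESAMPLES,
                           seed: int = 0) -> EnrichmentReport:
    """Permutation test of event-class composition of ``selected``.

    Draws ``resamples`` random subsets of ``len(selected)`` exons from the
    universe without replacement and compares the per-class counts with the
    observed ones, one-sided in the direction stated in ``DIRECTIONS``.
    """
    universe = list(universe)
    sel = set(selected)
    if not sel:
        raise ValueError("selected set is empty")
    if not sel <= set(universe):
        raise ValueError("selected exons must be a subset of the universe")
    n_sel = len(sel)
    if n_sel > len(universe):
        raise ValueError("selected set larger than universe")

    type_index = {t: i for i, t in enumerate(EVENT_TYPES)}
    codes = np.array([type_index[labels[e]] for e in universe], dtype=np.int64)
    sel_mask = np.array([e in sel for e in universe])
    observed = np.bincount(codes[sel_mask], minlength=len(EVENT_TYPES))
    universe_counts = np.bincount(codes, minlength=len(EVENT_TYPES))

    rng = np.random.default_rng(seed)
    bg = np.empty((resamples, len(EVENT_TYPES)), dtype=np.int64)
    n_univ = len(universe)
    for r in range(resamples):
        pick = rng.choice(n_univ, size=n_sel, replace=False)
        bg[r] = np.bincount(codes[pick], minlength=len(EVENT_TYPES))

    rows = []
    for t, ti in type_index.items():
        direction = DIRECTIONS[t]
        if direction == "greater":
            extreme = int((bg[:, ti] >= observed[ti]).sum())
        else:
            extreme = int((bg[:, ti] <= observed[ti]).sum())
        p = (1 + extreme) / (resamples + 1)
        rows.append({
            "event_type": t,
            "universe_count": int(universe_counts[ti]),
            "selected_count": int(observed[ti]),
            "mean_background": float(bg[:, ti].mean()),
            "p_value": round(p, 3),
            "direction": direction,
        })
    table = pd.DataFrame(rows).set_index("event_type")
    return EnrichmentReport(table=table, resamples=resamples, seed=seed)


def write_enrichment_tsv(report: EnrichmentReport, path: str) -> None:
    report.table.to_csv(path, sep="\t")
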