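"""Overall genome relatedness indices: fragment ANI and species-synonymy calls.

ANI is estimated classically: the query genome is cut into non-overlapping
~1 kb fragments, each fragment is aligned (edit distance, both strands)
against the subject genome, and ANI is the mean identity of the fragments
that align well enough. dDDH is never computed here — published values are
ingested from tables and combined with ANI by an explicit decision rule:
ANI >= 95% screens candidate synonym pairs, ANI > 96% plus dDDH >= 70%
calls a synonym, dDDH < 70% keeps the names distinct.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import edlib

from .markers import reverse_complement
from .records import GenomeRecord, OgriRecord, SynonymyCall

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AniParams:
    frag_len: int = 1020
    min_frag_identity: float = 0.3
    min_frag_aln_frac: float = 0.7
    symmetric: bool = True


def _one_way_ani(a: GenomeRecord, b: GenomeRecord, p: AniParams) -> tuple[float | None, int]:
    targets = [seq for _, seq in b.contigs]
    targets += [reverse_complement(seq) for seq in targets]
    identities = []
    max_k = int(p.frag_len * (1 - p.min_frag_identity)) + 1
    for _, seq in a.contigs:
        for off in range(0, len(seq) - p.frag_len + 1, p.frag_len):
            frag = seq[off:off + p.frag_len]
            best = None
            for t in targets:
                res = edlib.align(frag, t, mode="HW", task="locations", k=max_k)
                if res["editDistance"] < 0:
                    continue
                loc = res["locations"][0]
                span = loc[1] - loc[0] + 1
                aln_len = max(span, p.frag_len)
                ident = 1.0 - res["editDistance"] / aln_len
                aln_frac = min(span, p.frag_len) / p.frag_len
                if aln_frac < p.min_frag_aln_frac or ident < p.min_frag_identity:
                    continue
                if best is None or ident > best:
                    best = ident
            if best is not None:
                identities.append(best)
    if not identities:
        return None, 0
    return 100.0 * sum(identities) / len(identities), len(identities)


def estimate_ani(a: GenomeRecord, b: GenomeRecord,
                 params: AniParams = AniParams()) -> OgriRecord:
    """Fragment-based ANI between two genomes (symmetric mode averages both
    directions). A pair where no fragment aligns is returned with ANI absent
    and flagged not comparable."""
    ani_ab, n_ab = _one_way_ani(a, b, params)
    if params.symmetric:
        ani_ba, n_ba = _one_way_ani(b, a, params)
    else:
        ani_ba, n_ba = ani_ab, 0
    vals = [v for v in (ani_ab, ani_ba) if v is not None]
    if not vals:
        logger.warning("pair (%s, %s) not comparable: no fragment aligned",
                       a.strain_id, b.strain_id)
        return OgriRecord(strain_a=a.strain_id, strain_b=b.strain_id,
                          ani_pct=None, aligned_fragment_count=0,
                          note="not comparable")
    return OgriRecord(strain_a=a.strain_id, strain_b=b.strain_id,
                      ani_pct=sum(vals) / len(vals),
                      aligned_fragment_count=n_ab + n_ba)


@dataclass(frozen=True)
class SynonymyThresholds:
    """ANI >= ani_screen shortlists a pair; ANI > ani_species with
    dDDH >= dddh calls a synonym; dDDH < dddh keeps the pair distinct."""

    ani_screen: float = 95.0
    ani_species: float = 96.0
    dddh: float = 70.0


def classify_pair(r: OgriRecord,
                  thresholds: SynonymyThresholds = SynonymyThresholds()) -> SynonymyCall:
    """Apply the synonymy decision rule to one pair; the rule trace records
    every comparison so the verdict is auditable."""
    if r.ani_pct is None:
        raise ValueError(f"pair {r.pair} has no ANI value")
    t = thresholds
    trace: list[tuple[str, float | None, str, bool]] = []

    below_screen = r.ani_pct < t.ani_screen
    trace.append(("ani_screen", r.ani_pct, f"< {t.ani_screen}", below_screen))
    if below_screen:
        return SynonymyCall(pair=r.pair, verdict="distinct", rule_trace=trace)

    if r.dddh_pct is None:
        trace.append(("dddh_available", None, "present", False))
        return SynonymyCall(pair=r.pair, verdict="needs_dddh", rule_trace=trace)
    trace.append(("dddh_available", r.dddh_pct, "present", True))

    dddh_high = r.dddh_pct >= t.dddh
    ani_high = r.ani_pct > t.ani_species
    trace.append(("dddh", r.dddh_pct, f">= {t.dddh}", dddh_high))
    trace.append(("ani_species", r.ani_pct, f"> {t.ani_species}", ani_high))
    if dddh_high and ani_high:
        verdict = "synonym"
    elif not dddh_high:
        verdict = "distinct"
    else:
        verdict = "conflict"  # dDDH high but ANI at/below species cut-off
    return SynonymyCall(pair=r.pair, verdict=verdict, rule_trace=trace)


@dataclass
class SynonymyReport:
    thresholds: SynonymyThresholds
    screened: list[tuple[OgriRecord, SynonymyCall]]
    counts: dict[str, int] = field(default_factory=dict)

    def to_text(self) -> str:
        t = self.thresholds
        lines = [
            f"Species synonymy screen (ANI >= {t.ani_screen}%, species cut-off "
            f"ANI > {t.ani_species}%, dDDH >= {t.dddh}%)",
            f"screened pairs: {len(self.screened)}",
        ]
        for verdict in ("synonym", "distinct", "needs_dddh", "conflict"):
            lines.append(f"  {verdict}: {self.counts.get(verdict, 0)}")
        lines.append("")
        lines.append("pair\tani\tdddh\tverdict")
        for rec, call in self.screened:
            dddh = "" if rec.dddh_pct is None else f"{rec.dddh_pct:g}"
            lines.append(f"{rec.strain_a} | {rec.strain_b}\t{rec.ani_pct:.2f}\t"
                         f"{dddh}\t{call.verdict}")
        return "\n".join(lines) + "\n"


def synonymy_report(records: list[OgriRecord],
                    thresholds: SynonymyThresholds = SynonymyThresholds()) -> SynonymyReport:
    """Screen pairs at the ANI threshold and classify each, ordered by
    descending ANI."""
    seen: set[tuple[str, str]] = set()
    for r in records:
        if r.pair in seen:
            raise ValueError(f"duplicate pair {r.pair}")
        seen.add(r.pair)
    screened = [r for r in records
                if r.ani_pct is not None and r.ani_pct >= thresholds.ani_screen]
    screened.sort(key=lambda r: (-r.ani_pct, r.pair))
    calls = [(r, classify_pair(r, thresholds)) for r in screened]
    counts: dict[str, int] = {}
    for _, c in calls:
        counts[c.verdict] = counts.get(c.verdict, 0) + 1
    return SynonymyReport(thresholds=thresholds, screened=calls, counts=counts)
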