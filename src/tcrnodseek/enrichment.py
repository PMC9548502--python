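"""Shared/exclusive clone analysis, enriched CDR3β selection and motifs.

Sharing is assessed at the level of exact clone-key identity (by default the
CDR3β amino-acid sequence).  The enriched set combines each subject's
top-ranked clonotypes with the pooled top clonotypes across subjects, then
keeps sequences observed in at least ``min_subjects`` subjects.  Common
motifs are maximal substrings shared by many enriched sequences.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .errors import ConfigError, ValidationError
from .io import DEFAULT_CLONE_KEY, Repertoire


@dataclass
class SharingIndex:
    """Clone key → subjects carrying it, plus group membership of subjects."""

    carriers: dict[tuple, frozenset]
    groups: dict[str, frozenset]  # group name -> subject ids
    clone_key_fields: tuple[str, ...] = DEFAULT_CLONE_KEY

    @property
    def n_clones(self) -> int:
        return len(self.carriers)


def build_sharing_index(
    repertoires,
    metadata,
    clone_key=DEFAULT_CLONE_KEY,
) -> SharingIndex:
    """Index exact clone-key matches across subjects.

    Groups are derived from metadata: the two class labels plus, for
    malignant subjects, their tumour stage.
    """
    meta = {m.subject_id: m for m in metadata}
    missing = [r.subject_id for r in repertoires if r.subject_id not in meta]
    if missing:
        raise ValidationError(f"subjects missing from metadata: {missing}")
    carriers: dict[tuple, set] = {}
    for rep in repertoires:
        for rec in rep.records:
            carriers.setdefault(rec.key(clone_key), set()).add(rep.subject_id)
    groups: dict[str, set] = {}
    for rep in repertoires:
        m = meta[rep.subject_id]
        groups.setdefault(m.label, set()).add(m.subject_id)
        if m.stage is not None:
            groups.setdefault(m.stage, set()).add(m.subject_id)
    return SharingIndex(
        carriers={k: frozenset(v) for k, v in carriers.items()},
        groups={g: frozenset(v) for g, v in groups.items()},
        clone_key_fields=tuple(clone_key),
    )


def group_exclusive_clones(
    index: SharingIndex, target_group: str
) -> tuple[set, float]:
    """Clones carried only by subjects of *target_group*.

    Returns the set of exclusive clone keys and the exclusive fraction,
    i.e. |exclusive| / |all distinct clone keys|.
    """
    if target_group not in index.groups:
        raise ValidationError(
            f"unknown group {target_group!r}; known: {sorted(index.groups)}"
        )
    members = index.groups[target_group]
    exclusive = {
        k for k, subs in index.carriers.items() if subs and subs <= members
    }
    total = index.n_clones
    return exclusive, (len(exclusive) / total if total else 0.0)


@dataclass
class EnrichedSet:
    """Ordered enriched CDR3β sequences with per-sequence provenance."""

    sequences: list[str]
    provenance: pd.DataFrame = field(repr=False)  # sequence, rules, n_subjects

    def __len__(self) -> int:
        return len(self.sequences)


def _top_sequences(rep: Repertoire, n: int) -> list[str]:
    """Top-n CDR3β sequences by clonal fraction.

    Ties break by count desc then lexicographic sequence; duplicates (same
    sequence, different V/J) contribute their summed fraction once.
    """
    agg: dict[str, int] = {}
    for rec in rep.records:
        agg[rec.cdr3_aa] = agg.get(rec.cdr3_aa, 0) + rec.count
    ranked = sorted(agg.items(), key=lambda kv: (-kv[1], kv[0]))
    return [seq for seq, _ in ranked[:n]]


def select_enriched_sequences(
    repertoires,
    top_per_subject: int = 30,
    top_pooled: int = 3000,
    min_subjects: int = 2,
) -> EnrichedSet:
    """Enriched CDR3β amino-acid sequences of a group of repertoires.

    The candidate set is the union of (a) each subject's ``top_per_subject``
    sequences by clonal fraction and (b) the ``top_pooled`` sequences by
    fraction summed across subjects; candidates present in at least
    ``min_subjects`` subjects are retained.  With ``min_subjects=1`` the
    subject-support filter is disabled.  The result is invariant to the
    order of the input repertoires.
    """
    reps = list(repertoires)
    if min_subjects > len(reps):
        raise ConfigError(
            f"min_subjects={min_subjects} exceeds the {len(reps)} subjects given"
        )
    if top_per_subject < 0 or top_pooled < 0 or min_subjects < 1:
        raise ConfigError("selection parameters must be positive")

    support: dict[str, set] = {}
    pooled: dict[str, float] = {}
    for rep in reps:
        f = rep.fractions
        for rec, frac in zip(rep.records, f):
            support.setdefault(rec.cdr3_aa, set()).add(rep.subject_id)
            pooled[rec.cdr3_aa] = pooled.get(rec.cdr3_aa, 0.0) + float(frac)

    rules: dict[str, set] = {}
    for rep in reps:
        for seq in _top_sequences(rep, top_per_subject):
            rules.setdefault(seq, set()).add("top30")
    pooled_ranked = sorted(pooled.items(), key=lambda kv: (-kv[1], kv[0]))
    for seq, _ in pooled_ranked[:top_pooled]:
        rules.setdefault(seq, set()).add("top3000")

    kept = [s for s in rules if len(support[s]) >= min_subjects]
    kept.sort(key=lambda s: (-pooled[s], s))
    prov = pd.DataFrame(
        {
            "sequence": kept,
            "rules": ["+".join(sorted(rules[s])) for s in kept],
            "n_subjects": [len(support[s]) for s in kept],
            "pooled_fraction": [pooled[s] for s in kept],
        }
    )
    return EnrichedSet(sequences=kept, provenance=prov)


@dataclass(frozen=True)
class MotifResult:
    """A maximal common substring of the enriched sequences."""

    motif: str
    support: int  # number of distinct enriched sequences containing it
    length: int


def find_common_motifs(
    sequences, min_length: int = 5, min_support: int = 2
) -> list[MotifResult]:
    """Maximal common amino-acid substrings of a set of sequences.

    Returns every substring of length >= ``min_length`` contained in at
    least ``min_support`` distinct sequences, such that no longer substring
    has the same support set (maximality).  Results are ranked by support
    desc, then length desc, then lexicographically.
    """
    if hasattr(sequences, "sequences"):
        sequences = sequences.sequences
    seqs = sorted(set(sequences))
    if not seqs:
        raise ValidationError("empty sequence set")
    if min_length < 3:
        raise ConfigError("min_length must be >= 3")

    support: dict[str, int] = {}
    for seq in seqs:
        seen = set()
        n = len(seq)
        for length in range(min_length, n + 1):
            for start in range(n - length + 1):
                seen.add(seq[start : start + length])
        for sub in seen:
            support[sub] = support.get(sub, 0) + 1

    # a substring is non-maximal iff a one-character extension occurs with an
    # identical support count (support sets are nested, so counts suffice)
    non_maximal = set()
    for sub, cnt in support.items():
        if len(sub) > min_length:
            for shorter in (sub[:-1], sub[1:]):
                if support.get(shorter) == cnt:
                    non_maximal.add(shorter)

    results = [
        MotifResult(motif=s, support=c, length=len(s))
        for s, c in support.items()
        if c >= min_support and s not in non_maximal
    ]
    results.sort(key=lambda m: (-m.support, -m.length, m.motif))
    return results
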