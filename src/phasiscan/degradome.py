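"""Degradome (PARE) tag profiles, cleavage-site categories, target calling.

Degradome sequencing captures the 5' ends of uncapped, polyadenylated
mRNA fragments; a sliced target leaves a tag whose 5' end coincides with
the target base paired to sRNA position 10.  A candidate duplex is
"validated" when that diagnostic position carries a Category 0 or 1
signal of at least 4 tags making up at least 10% of all tags on the
transcript - thresholds applied inclusively, exactly as stated.

Categories rank the cleavage-site tag count against the transcript's tag
profile: 0 unique maximum (>1 tags), 1 tied maximum, 2 above average,
3 above 1 but at most average, 4 single tag.  "Average" is computed over
occupied positions (those with >= 1 tag) by default; ``average="all"``
divides by every nucleotide position instead and is flagged in outputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .seqtools import is_unambiguous, normalize
from .srna import normalize_rp10m
from .targets import DuplexAlignment


@dataclass
class DegradomeTag:
    """A collapsed degradome tag: transcript, 1-based 5' position, count."""

    transcript_id: str
    position: int  # 1-based 5'-end coordinate
    count: int
    sequence: str = ""


class DegradomeProfile:
    """Per-transcript counts of degradome-tag 5' ends (1-based positions)."""

    def __init__(self, transcript_id: str, length: int | None = None) -> None:
        self.transcript_id = transcript_id
        self.length = length
        self.counts: dict[int, float] = {}

    def add(self, position: int, count: float) -> None:
        self.counts[position] = self.counts.get(position, 0.0) + count

    def get(self, position: int) -> float:
        return self.counts.get(position, 0.0)

    @property
    def total_tags(self) -> float:
        return sum(self.counts.values())

    def rp10m(self, position: int, library_total: float) -> float:
        return normalize_rp10m(self.get(position), library_total)


@dataclass
class CleavageCall:
    """Outcome of checking one candidate duplex against a tag profile."""

    srna_id: str
    transcript_id: str
    site: int  # 1-based cleavage (+1) coordinate
    tags_at_site: float
    category: int | None
    site_fraction: float
    validated: bool
    duplex_score: float
    rp10m_at_site: float | None = None


def map_tags(
    tags: Iterable[tuple[str, int]] | Iterable[DegradomeTag],
    transcriptome: Mapping[str, str],
    min_tag_len: int = 15,
) -> tuple[dict[str, DegradomeProfile], int]:
    """Place sequence tags on transcripts by exact sense-strand match.

    ``tags`` is an iterable of (sequence, count) pairs or DegradomeTag
    records carrying sequences.  A tag matching several transcripts
    contributes to each (count-all).  Returns (profiles keyed by
    transcript id, number of unmapped tag species).  Tags shorter than
    ``min_tag_len`` or containing ambiguity codes are skipped.
    """
    profiles = {
        tid: DegradomeProfile(tid, len(seq)) for tid, seq in transcriptome.items()
    }
    norm_ref = {tid: normalize(seq) for tid, seq in transcriptome.items()}
    unmapped = 0
    for tag in tags:
        if isinstance(tag, DegradomeTag):
            seq, count = tag.sequence, tag.count
        else:
            seq, count = tag
        seq = normalize(seq)
        if len(seq) < min_tag_len:
            warnings.warn(f"skipping degradome tag shorter than {min_tag_len} nt")
            continue
        if not is_unambiguous(seq):
            continue
        hit = False
        for tid, ref in norm_ref.items():
            start = ref.find(seq)
            while start != -1:
                profiles[tid].add(start + 1, count)
                hit = True
                start = ref.find(seq, start + 1)
        if not hit:
            unmapped += 1
    return profiles, unmapped


def profiles_from_records(
    records: Iterable[DegradomeTag],
    transcript_lengths: Mapping[str, int] | None = None,
) -> dict[str, DegradomeProfile]:
    """Build profiles from positional (transcript, position, count) records."""
    profiles: dict[str, DegradomeProfile] = {}
    for rec in records:
        prof = profiles.get(rec.transcript_id)
        if prof is None:
            length = (
                transcript_lengths.get(rec.transcript_id)
                if transcript_lengths
                else None
            )
            prof = profiles[rec.transcript_id] = DegradomeProfile(
                rec.transcript_id, length
            )
        prof.add(rec.position, rec.count)
    return profiles


def categorize_site(
    profile: DegradomeProfile, position: int, average: str = "occupied"
) -> int:
    """Assign the Category 0-4 rank of the tag count at ``position``.

    ``average`` selects the denominator of the mean tag count: "occupied"
    (positions with >= 1 tag; default) or "all" (every nucleotide, which
    requires the profile to know its transcript length).
    """
    c = profile.get(position)
    if c < 1:
        raise ValueError(
            f"no degradome tag at {profile.transcript_id}:{position}; category undefined"
        )
    if c == 1:
        return 4
    values = list(profile.counts.values())
    mx = max(values)
    if average == "occupied":
        mean = sum(values) / len(values)
    elif average == "all":
        if not profile.length:
            raise ValueError('average="all" requires the transcript length')
        mean = sum(values) / profile.length
    else:
        raise ValueError(f"unknown average mode: {average}")
    if c == mx:
        n_at_max = sum(1 for v in values if v == mx)
        return 0 if n_at_max == 1 else 1
    if c > mean:
        return 2
    return 3


def validate_cleavage(
    candidate: DuplexAlignment,
    profile: DegradomeProfile | None,
    min_tags: float = 4,
    min_fraction: float = 0.10,
    library_total: float | None = None,
    average: str = "occupied",
) -> CleavageCall:
    """Check a candidate duplex against the degradome profile of its target.

    validated <=> category in {0, 1} and tags_at_site >= min_tags and
    tags_at_site / total_tags >= min_fraction (both bounds inclusive).
    Sites outside the profile, or candidates without a defined cleavage
    coordinate, yield an unvalidated call with zero tags.
    """
    site = candidate.cleavage_site
    if site is None:
        raise ValueError("candidate has no defined cleavage coordinate")
    tags = profile.get(site) if profile is not None else 0.0
    total = profile.total_tags if profile is not None else 0.0
    if tags >= 1:
        category: int | None = categorize_site(profile, site, average=average)
    else:
        category = None
    fraction = tags / total if total > 0 else 0.0
    validated = (
        category in (0, 1) and tags >= min_tags and fraction >= min_fraction
    )
    rp10m = None
    if library_total and library_total > 0:
        rp10m = normalize_rp10m(tags, library_total)
    return CleavageCall(
        srna_id=candidate.srna_id,
        transcript_id=candidate.target_id,
        site=site,
        tags_at_site=tags,
        category=category,
        site_fraction=fraction,
        validated=validated,
        duplex_score=candidate.score,
        rp10m_at_site=rp10m,
    )


def call_targets(
    candidates: Sequence[DuplexAlignment],
    profiles: Mapping[str, DegradomeProfile],
    library_total: float | None = None,
    min_tags: float = 4,
    min_fraction: float = 0.10,
    average: str = "occupied",
):
    """Validate every candidate; return the target table as a DataFrame.

    Columns follow the reporting convention (1-based site, duplex score,
    tags at site, RP10M, category, site fraction, validated flag), sorted
    by transcript then site.
    """
    import pandas as pd

    rows = []
    for cand in candidates:
        if cand.cleavage_pos0 is None:
            continue
        call = validate_cleavage(
            cand,
            profiles.get(cand.target_id),
            min_tags=min_tags,
            min_fraction=min_fraction,
            library_total=library_total,
            average=average,
        )
        rows.append(
            {
                "srna_id": call.srna_id,
                "transcript_id": call.transcript_id,
                "site": call.site,
                "duplex_score": call.duplex_score,
                "tags_at_site": call.tags_at_site,
                "rp10m": call.rp10m_at_site,
                "category": call.category,
                "site_fraction": call.site_fraction,
                "validated": call.validated,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "srna_id",
            "transcript_id",
            "site",
            "duplex_score",
            "tags_at_site",
            "rp10m",
            "category",
            "site_fraction",
            "validated",
        ],
    )
    if len(df):
        df = df.sort_values(
            ["transcript_id", "site", "srna_id"], kind="mergesort"
        ).reset_index(drop=True)
    return df


def tplot_table(profile: DegradomeProfile, library_total: float | None = None):
    """Per-position tag counts of one transcript (t-plot data) as a DataFrame."""
    import pandas as pd

    rows = [
        {
            "transcript_id": profile.transcript_id,
            "position": pos,
            "tags": cnt,
            "rp10m": normalize_rp10m(cnt, library_total)
            if library_total
            else None,
        }
        for pos, cnt in sorted(profile.counts.items())
    ]
    return pd.DataFrame(rows, columns=["transcript_id", "position", "tags", "rp10m"])
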