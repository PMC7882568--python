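"""Dominant-mediator profiles per game type.

A game type's profile is decided from the statistically relevant, positive
indirect effects of its mediation fit: effects whose percentile bootstrap CI
excludes zero *and* whose point estimate is positive are ranked by estimate
(descending; ties broken by fixed mediator order M1..M6). The largest is the
dominant mediator; the dominance ratio divides the largest by the
second-largest (undefined with fewer than two such effects; computed on
unrounded estimates). A ratio below the threshold (default 2.0) marks the
profile as equivocal; otherwise the profile is named after the dominant
mediator: breadth-dominant, frequency-within-dominant, or other-dominant.
Negative indirect effects never enter the ranking regardless of magnitude --
the classification concerns problem-increasing mechanisms only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .features import MEDIATOR_COLUMNS
from .mediation import MediationFit

PROFILE_LABELS = (
    "breadth_dominant",
    "frequency_within_dominant",
    "other_dominant",
    "equivocal",
    "none_relevant",
)

#: mediator -> profile label when it dominates
_DOMINANT_LABEL = {
    "M2_breadth": "breadth_dominant",
    "M3_freq_within": "frequency_within_dominant",
}


@dataclass
class MediatorProfile:
    """Classification of one game type by its dominant mediating mechanism."""

    type_id: str
    relevant_positive: list  # [(mediator, estimate)], descending
    dominant: str | None
    dominance_ratio: float | None  # None when fewer than two relevant effects
    profile: str
    threshold: float = 2.0


def classify(
    fit: MediationFit,
    threshold: float = 2.0,
    mediator_labels: dict | None = None,
) -> MediatorProfile:
    """Classify one mediation fit by its largest relevant positive indirect effect.

    ``mediator_labels`` optionally maps mediator names to profile labels for
    non-default mediator sets; by default breadth and frequency-within map to
    their named profiles and any other dominant mediator to ``other_dominant``.
    """
    label_map = dict(_DOMINANT_LABEL)
    if mediator_labels:
        label_map.update(mediator_labels)

    order = {m: i for i, m in enumerate(fit.mediators)}
    relevant = []
    for med, est in fit.indirect_effects().items():
        flag = fit.relevant.get(f"indirect:{med}", False)
        if flag and est > 0:
            relevant.append((med, float(est)))
    # descending by estimate; ties broken by fixed mediator order
    relevant.sort(key=lambda t: (-t[1], order[t[0]]))

    if not relevant:
        return MediatorProfile(
            type_id=fit.focal_type or "",
            relevant_positive=[],
            dominant=None,
            dominance_ratio=None,
            profile="none_relevant",
            threshold=threshold,
        )
    dominant = relevant[0][0]
    ratio = relevant[0][1] / relevant[1][1] if len(relevant) >= 2 else None
    if ratio is not None and ratio < threshold:
        profile = "equivocal"
    else:
        profile = label_map.get(dominant, "other_dominant")
    return MediatorProfile(
        type_id=fit.focal_type or "",
        relevant_positive=relevant,
        dominant=dominant,
        dominance_ratio=ratio,
        profile=profile,
        threshold=threshold,
    )


@dataclass
class ProfileSummary:
    """Tabulation of profile labels with per-label type memberships."""

    counts: dict  # label -> count
    members: dict  # label -> [type_id]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "profile": list(self.counts),
                "count": list(self.counts.values()),
                "types": [", ".join(self.members[k]) for k in self.counts],
            }
        )

    def to_text(self) -> str:
        lines = []
        for label in PROFILE_LABELS:
            if self.counts.get(label, 0):
                lines.append(f"{label} ({self.counts[label]}):")
                for t in self.members[label]:
                    lines.append(f"  - {t}")
        return "\n".join(lines) if lines else "(no profiles)"


def summarize_profiles(profiles) -> ProfileSummary:
    """Count profile labels and list member game types per label."""
    counts = {label: 0 for label in PROFILE_LABELS}
    members = {label: [] for label in PROFILE_LABELS}
    for p in profiles:
        counts[p.profile] += 1
        members[p.profile].append(p.type_id)
    return ProfileSummary(counts=counts, members=members)


def profiles_frame(profiles) -> pd.DataFrame:
    """Tidy per-type profile table (type, dominant mediator, ratio, label)."""
    return pd.DataFrame(
        [
            {
                "type_id": p.type_id,
                "dominant": p.dominant,
                "dominance_ratio": p.dominance_ratio,
                "profile": p.profile,
            }
            for p in profiles
        ]
    )
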