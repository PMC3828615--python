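"""Synthetic worked fixtures mirroring the published arithmetic.

These are hand-constructed inputs (no randomness, no real patient data) whose
pipeline outputs reproduce the headline bookkeeping of the bladder-cancer
marker study: a 38-marker deep-sequencing fixture yielding 33/38 directional
agreements (86.8%, printed as 87%) with a (20 up, 15 down, 3 mixed) tally,
and a three-method congruence fixture where exactly one marker (mir205) is
called UP by every assay.  Marker names are real miRNA names from the
bladder-cancer literature; every ratio value is invented.
"""

from __future__ import annotations

from .diffexp import RatioProfile, Status, StatusCall, Tier
from .marker_db import MarkerRecord, MarkerType, PublishedStatus

# 18 markers published UP whose profiles vote UP at the SOFT tier
_AGREE_UP = [
    "mir183", "mir205", "mir96", "mir20a", "mir106b", "mir130b",
    "mir141", "mir200a", "mir200b", "mir200c", "mir429", "mir17",
    "mir18a", "mir19a", "mir210", "mir182", "mir224", "mir21",
]
# 15 markers published DOWN whose profiles vote DOWN
_AGREE_DOWN = [
    "mir100", "mir125b", "mir143", "let7c", "mir199a", "mir199a2",
    "mir145", "mir101", "mir99a", "mir29c", "mir30a", "mir30c",
    "mir133a", "mir133b", "mir195",
]
# 2 markers published DOWN whose profiles vote UP (directional disagreements)
_DISAGREE_UP = ["mir126", "mir146a"]
# 3 markers with balanced up/down votes (MIXED, non-directional)
_MIXED = ["mir10", "mir34a", "mir493"]

_UP_PATTERN = [2.6, 3.1, 3.7, 4.2, 4.8, 5.3, 2.9, 3.4, 6.0]
_DOWN_PATTERN = [0.38, 0.31, 0.27, 0.23, 0.20, 0.18, 0.34, 0.29, 0.16]
_MIXED_PATTERN = [2.5, 3.0, 4.0, 0.45, 0.40, 0.30, 1.0, 1.2, 0.9]

_SAMPLES = [f"tumor_{i + 1:02d}" for i in range(9)]


def _profile(mirna: str, pattern: list[float], rotate: int) -> RatioProfile:
    values = pattern[rotate % len(pattern):] + pattern[: rotate % len(pattern)]
    return RatioProfile(mirna_id=mirna, ratios=dict(zip(_SAMPLES, values)))


def worked_ds_fixture() -> tuple[list[MarkerRecord], dict[str, RatioProfile]]:
    """The 38-marker deep-sequencing worked example.

    Running ``vote_classify`` at the SOFT tier over these profiles and
    comparing against the catalogue yields 33 agreements out of 38 assessed
    markers (86.8%) and a direction tally of 20 up, 15 down, 3 mixed.
    """
    catalogue: list[MarkerRecord] = []
    profiles: dict[str, RatioProfile] = {}
    for i, mirna in enumerate(_AGREE_UP):
        catalogue.append(MarkerRecord(mirna, PublishedStatus.UP))
        profiles[mirna] = _profile(mirna, _UP_PATTERN, i)
    for i, mirna in enumerate(_AGREE_DOWN):
        catalogue.append(MarkerRecord(mirna, PublishedStatus.DOWN))
        profiles[mirna] = _profile(mirna, _DOWN_PATTERN, i)
    for i, mirna in enumerate(_DISAGREE_UP):
        catalogue.append(MarkerRecord(mirna, PublishedStatus.DOWN))
        profiles[mirna] = _profile(mirna, _UP_PATTERN, i + 3)
    for i, mirna in enumerate(_MIXED):
        catalogue.append(MarkerRecord(mirna, PublishedStatus.UP))
        profiles[mirna] = _profile(mirna, _MIXED_PATTERN, 3 * i)
    return catalogue, profiles


def _call(mirna: str, status: Status, method: str) -> StatusCall:
    return StatusCall(
        mirna_id=mirna,
        status=status,
        up_votes=int(status == Status.UP),
        down_votes=int(status == Status.DOWN),
        neutral_votes=int(status == Status.NEUTRAL),
        method=method,
    )


def congruence_fixture() -> tuple[list[MarkerRecord], dict[str, dict[str, StatusCall]]]:
    """A three-method congruence example with a single full agreement.

    mir205 is called UP by deep sequencing, SSH and the microarray alike
    (and published UP); every other marker lacks at least one directional
    agreement, so exactly one congruence cell contains all three methods.
    """
    catalogue = [
        MarkerRecord("mir205", PublishedStatus.UP),
        MarkerRecord("mir141", PublishedStatus.CONTRADICTORY),
        MarkerRecord("mir100", PublishedStatus.DOWN),
        MarkerRecord("mir143", PublishedStatus.DOWN),
        MarkerRecord("mir199a", PublishedStatus.DOWN),
        MarkerRecord("mir21", PublishedStatus.UP),
    ]
    plan = {
        # mirna: (DS, SSH, MA)
        "mir205": (Status.UP, Status.UP, Status.UP),
        "mir141": (Status.DOWN, Status.DOWN, Status.NEUTRAL),
        "mir100": (Status.DOWN, Status.NEUTRAL, Status.NEUTRAL),
        "mir143": (Status.DOWN, Status.UP, Status.NEUTRAL),
        "mir199a": (Status.NEUTRAL, Status.NEUTRAL, Status.NEUTRAL),
        "mir21": (Status.MIXED, Status.DOWN, Status.NEUTRAL),
    }
    calls: dict[str, dict[str, StatusCall]] = {"DS": {}, "SSH": {}, "MA": {}}
    for mirna, (ds, ssh, ma) in plan.items():
        calls["DS"][mirna] = _call(mirna, ds, "DS")
        calls["SSH"][mirna] = _call(mirna, ssh, "SSH")
        calls["MA"][mirna] = _call(mirna, ma, "MA")
    return catalogue, calls


SOFT = Tier.SOFT  # convenience re-export for example scripts
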