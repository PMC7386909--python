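"""Registry of the 32 NK-cell phenotypic features.

Each feature is a flow-cytometry-derived percentage describing an NK-cell
subset: CD56dim/CD56bright density subsets and their CD16 composition,
CD8 co-expression, and the activating (NKp30, NKp46, NKp44, DNAM-1, NKG2D,
2B4) and inhibitory (CD85j, LAIR-1, NKG2A) receptor repertoire.

Marker-positive/marker-negative pairs within a parent gate are complements:
their percentages sum to ~100.  The registry records that pairing plus the
compositional CD16 blocks used by the synthetic generator.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "FeatureDescriptor",
    "FEATURES",
    "COMPLEMENT_PAIRS",
    "feature",
    "feature_name",
    "PSA_ID",
]

#: Pseudo feature id used to denote the PSA column in predictor sets.
PSA_ID = 0


@dataclass(frozen=True)
class FeatureDescriptor:
    """One phenotypic feature: numeric id, display name, panel group and
    (optionally) the id of its marker-negative/positive complement."""

    id: int
    name: str
    panel_group: str
    complement_partner: int | None = None


# (id, name, panel group, complement partner)
_RAW = [
    (1, "CD56dim CD16+", "CD56dim", None),
    (2, "CD56dim CD16high", "CD56dim", None),
    (3, "CD56dim CD16low", "CD56dim", None),
    (4, "CD56dim CD16-", "CD56dim", None),
    (5, "CD56dim total", "CD56dim", 10),
    (6, "CD56bright CD16+", "CD56bright", None),
    (7, "CD56bright CD16high", "CD56bright", None),
    (8, "CD56bright CD16low", "CD56bright", None),
    (9, "CD56bright CD16-", "CD56bright", None),
    (10, "CD56bright total", "CD56bright", 5),
    (11, "CD56+ CD8+", "CD8", 12),
    (12, "CD56+ CD8-", "CD8", 11),
    (13, "CD56dim CD8+", "CD8", None),
    (14, "CD56bright CD8+", "CD8", None),
    (15, "CD56+ NKp30+", "NKp30", 16),
    (16, "CD56+ NKp30-", "NKp30", 15),
    (17, "CD56+ NKp46+", "NKp46", 18),
    (18, "CD56+ NKp46-", "NKp46", 17),
    (19, "CD56+ DNAM-1+", "DNAM-1", 20),
    (20, "CD56+ DNAM-1-", "DNAM-1", 19),
    (21, "CD56+ NKG2D+", "NKG2D", 22),
    (22, "CD56+ NKG2D-", "NKG2D", 21),
    (23, "CD56+ NKp44+", "NKp44", 24),
    (24, "CD56+ NKp44-", "NKp44", 23),
    (25, "CD56+ CD85j+", "CD85j", 26),
    (26, "CD56+ CD85j-", "CD85j", 25),
    (27, "CD56+ LAIR-1+", "LAIR-1", 28),
    (28, "CD56+ LAIR-1-", "LAIR-1", 27),
    (29, "CD56+ NKG2A+", "NKG2A", 30),
    (30, "CD56+ NKG2A-", "NKG2A", 29),
    (31, "CD56+ 2B4+", "2B4", 32),
    (32, "CD56+ 2B4-", "2B4", 31),
]

FEATURES: tuple[FeatureDescriptor, ...] = tuple(
    FeatureDescriptor(i, n, g, p) for i, n, g, p in _RAW
)

#: Complement pairs (marker+ id, marker- id); the first member is the one
#: the synthetic generator simulates, the second is derived as 100 - x.
COMPLEMENT_PAIRS: tuple[tuple[int, int], ...] = (
    (5, 10),
    (11, 12),
    (15, 16),
    (17, 18),
    (19, 20),
    (21, 22),
    (23, 24),
    (25, 26),
    (27, 28),
    (29, 30),
    (31, 32),
)

_BY_ID = {f.id: f for f in FEATURES}


def feature(fid: int) -> FeatureDescriptor:
    """Return the descriptor for feature ``fid`` (1..32)."""
    try:
        return _BY_ID[fid]
    except KeyError:
        raise KeyError(f"unknown feature id {fid!r}; valid ids are 1..32") from None


def feature_name(fid: int) -> str:
    if fid == PSA_ID:
        return "PSA"
    return feature(fid).name
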