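"""Brain-region vocabulary.

The default vocabulary is the developmental-atlas region set used for the
regional analysis: transient fetal structures (ganglionic eminences, rhombic
lip, cerebral-wall samples) plus the mature cortical/subcortical sampling
grid. The *neurogenic* subset marks transient proliferative zones — the
caudal/lateral/medial ganglionic eminences and the upper rhombic lip — which
consist largely of neuronal precursors and immature migrating neurons.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import ValidationError

#: Developmental-atlas region codes (fetal transient + mature structures).
DEFAULT_REGION_CODES: frozenset[str] = frozenset(
    {
        "CGE", "DIE", "DTH", "FC", "LGE", "MGE", "OC", "PC", "TC", "URL", "VF",
        "A1C", "AMY", "CBC", "DFC", "HIP", "ITC", "M1C", "MD", "MFC", "OFC",
        "S1C", "STC", "STR", "V1C", "VFC",
    }
)

#: Transient proliferative (neurogenic) zones.
DEFAULT_NEUROGENIC: frozenset[str] = frozenset({"CGE", "LGE", "MGE", "URL"})


@dataclass
class RegionVocabulary:
    """Registered region codes with a flagged neurogenic subset."""

    codes: set[str] = field(default_factory=lambda: set(DEFAULT_REGION_CODES))
    neurogenic: set[str] = field(default_factory=lambda: set(DEFAULT_NEUROGENIC))

    def __post_init__(self) -> None:
        self.codes = set(self.codes)
        self.neurogenic = set(self.neurogenic)
        unknown = self.neurogenic - self.codes
        if unknown:
            raise ValidationError(
                f"neurogenic regions not in vocabulary: {sorted(unknown)}"
            )

    def register(self, code: str, neurogenic: bool = False) -> None:
        """Add a user-defined region code."""
        self.codes.add(code)
        if neurogenic:
            self.neurogenic.add(code)

    def validate(self, code: str) -> str:
        if code not in self.codes:
            raise ValidationError(
                f"region {code!r} is not in the vocabulary; "
                "register it explicitly if intended"
            )
        return code

    def __contains__(self, code: object) -> bool:
        return code in self.codes


def default_vocabulary() -> RegionVocabulary:
    return RegionVocabulary()
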