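"""The 13-class adulteration grading scheme.

Pure quince seed oil (PQ), five sunflower blends plus pure sunflower,
and five sesame blends plus pure sesame. "Su30:Q70" means 30% sunflower
oil blended into 70% quince seed oil; the mixture fraction is the
volume proportion of the adulterant.
"""

from __future__ import annotations

__all__ = ["CLASS_ORDER", "CLASS_DEFINITIONS", "class_label"]

#: (label, adulterant, mixture fraction) in canonical report order.
CLASS_DEFINITIONS: list[tuple[str, str, float]] = [
    ("PQ", "none", 0.0),
    ("Su10:Q90", "sunflower", 0.10),
    ("Su20:Q80", "sunflower", 0.20),
    ("Su30:Q70", "sunflower", 0.30),
    ("Su40:Q60", "sunflower", 0.40),
    ("Su50:Q50", "sunflower", 0.50),
    ("PSu", "sunflower", 1.0),
    ("Se10:Q90", "sesame", 0.10),
    ("Se20:Q80", "sesame", 0.20),
    ("Se30:Q70", "sesame", 0.30),
    ("Se40:Q60", "sesame", 0.40),
    ("Se50:Q50", "sesame", 0.50),
    ("PSe", "sesame", 1.0),
]

CLASS_ORDER: list[str] = [label for label, _, _ in CLASS_DEFINITIONS]


def class_label(adulterant: str, fraction: float) -> str:
    """Canonical class label for an (adulterant, fraction) pair."""
    for label, adu, frac in CLASS_DEFINITIONS:
        if adu == adulterant and abs(frac - fraction) < 1e-9:
            return label
        if fraction == 0.0 and label == "PQ":
            return "PQ"
    raise ValueError(f"no class for adulterant={adulterant!r}, fraction={fraction}")
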