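"""The fixed eight-category annotation scheme and its BIO tag space.

Categories follow the diabetes consultation-text standard: tests/examinations
(check), diseases, drugs, lifestyle (life), emotions (mood), socio-demographic
context (social), symptoms, and treatments (treat).  Character-level BIO
tagging over eight categories yields 17 tags: O plus B-x/I-x per category.
"""

from __future__ import annotations

from dataclasses import dataclass, field

CATEGORIES: tuple[str, ...] = (
    "check", "disease", "drug", "life", "mood", "social", "symptom", "treat",
)

OUTSIDE = "O"


@dataclass(frozen=True)
class LabelScheme:
    """BIO tag inventory for a fixed set of entity categories.

    Tag 0 is always O; each category contributes a B- and an I- tag in
    category order.  Tag indices are stable, which the CRF transition
    matrix and checkpoints rely on.
    """

    categories: tuple[str, ...] = CATEGORIES

    @property
    def tags(self) -> tuple[str, ...]:
        out = [OUTSIDE]
        for cat in self.categories:
            out.append(f"B-{cat}")
            out.append(f"I-{cat}")
        return tuple(out)

    @property
    def num_tags(self) -> int:
        return 1 + 2 * len(self.categories)

    def tag_index(self, tag: str) -> int:
        try:
            return self.tags.index(tag)
        except ValueError:
            raise KeyError(f"unknown tag {tag!r}") from None

    def index_tag(self, idx: int) -> str:
        return self.tags[idx]

    def validate_label(self, label: str) -> None:
        if label not in self.categories:
            raise ValueError(
                f"label {label!r} not in scheme {self.categories}")


DEFAULT_SCHEME = LabelScheme()
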