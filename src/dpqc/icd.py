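"""ICD-10 structural validation and the sex-specific code ranges.

Structural validity is a pattern test, not terminology membership: a letter
(``U`` excluded, as in ICD-10 chapter codes), two alphanumerics, and an
optional dotted suffix of up to four characters.  A user-supplied code list
can replace the pattern with terminology membership where a controlled
vocabulary is available.
"""

from __future__ import annotations

import re
from typing import Collection

ICD10_PATTERN = re.compile(r"^[A-TV-Z][0-9][0-9A-B](\.[0-9A-TV-Z]{1,4})?$")

# Male-only C60-C63 (male genital organs), female-only C51-C58 (female genital
# organs).  Category-level prefix match; extendable via configuration.
MALE_ONLY_CATEGORIES = frozenset({"C60", "C61", "C62", "C63"})
FEMALE_ONLY_CATEGORIES = frozenset({"C51", "C52", "C53", "C54", "C55", "C56", "C57", "C58"})

DEFAULT_INCOMPATIBILITY = {
    "male": FEMALE_ONLY_CATEGORIES,
    "female": MALE_ONLY_CATEGORIES,
}

#: Real ICD-10 category/subcategory codes used by the synthetic generator for
#: "valid" conditions.  Deliberately excludes the sex-specific C51-C63 range so
#: that incompatible diagnoses are only ever injected on purpose.
VALID_CODE_POOL = (
    "A09", "A41.9", "B18.2", "B20", "C16.9", "C18.7", "C25.9", "C34.9",
    "C43.9", "C50.9", "C64.9", "C71.9", "C78.0", "C80.1", "C90.0", "D50.9",
    "D64.9", "E03.9", "E10.9", "E11.9", "E66.9", "E78.5", "F03", "F32.9",
    "F41.1", "G20", "G30.9", "G40.9", "I10", "I21.9", "I25.1", "I48.9",
    "I50.9", "I63.9", "J18.9", "J44.9", "J45.9", "K21.9", "K50.9", "K70.3",
    "L40.9", "M05.9", "M54.5", "N18.9", "N39.0", "R50.9", "Z51.1", "E04.9",
    "I70.2", "K57.9",
)


def is_valid_icd10(code: str | None, code_list: Collection[str] | None = None) -> bool:
    """Structural pattern test, or membership when ``code_list`` is given.

    A missing code cannot be validated and counts as invalid.
    """
    if code is None:
        return False
    if code_list is not None:
        return code in code_list
    return ICD10_PATTERN.match(code) is not None


def category(code: str) -> str:
    """First three characters of a code: ``"C61"`` for ``"C61"``, ``"C50.9"`` -> ``"C50"``."""
    return code[:3]


def is_incompatible(
    gender: str | None,
    code: str | None,
    incompatibility: dict[str, frozenset[str]] | None = None,
) -> bool:
    """True when ``code`` belongs to a range excluded for the recorded gender."""
    if gender is None or code is None:
        return False
    table = DEFAULT_INCOMPATIBILITY if incompatibility is None else incompatibility
    excluded = table.get(gender)
    return excluded is not None and category(code) in excluded
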