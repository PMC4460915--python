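"""Controlled species vocabulary for Snapshot Serengeti classification tables.

Volunteers choose from 48 species and species-group options. Four of these
are group categories (``human``, ``other bird``, ``reptiles``, ``rodents``)
and lions are split into ``lion male`` and ``lion female&cub``. Two reserved
tokens extend the vocabulary in specific tables: ``blank`` ('nothing here')
may appear in raw classification tables, and ``impossible`` only in
gold-standard tables, where an expert panel may declare an image
unidentifiable.
"""

from __future__ import annotations

__all__ = [
    "SPECIES",
    "BLANK",
    "IMPOSSIBLE",
    "UnknownSpeciesError",
    "canonical_species",
    "is_species",
]

BLANK = "blank"
IMPOSSIBLE = "impossible"

#: The 48 species / species-group options, canonical spellings.
SPECIES: tuple[str, ...] = (
    "aardvark",
    "aardwolf",
    "baboon",
    "bat eared fox",
    "buffalo",
    "bushbuck",
    "caracal",
    "cheetah",
    "civet",
    "dik dik",
    "eland",
    "elephant",
    "genet",
    "giraffe",
    "grant's gazelle",
    "guinea fowl",
    "hare",
    "hartebeest",
    "hippopotamus",
    "honey badger",
    "human",
    "impala",
    "jackal",
    "kori bustard",
    "leopard",
    "lion female&cub",
    "lion male",
    "mongoose",
    "ostrich",
    "other bird",
    "porcupine",
    "reedbuck",
    "reptiles",
    "rhinoceros",
    "rodents",
    "secretary bird",
    "serval",
    "spotted hyena",
    "striped hyena",
    "thomson's gazelle",
    "topi",
    "vervet monkey",
    "warthog",
    "waterbuck",
    "wildcat",
    "wildebeest",
    "zebra",
    "zorilla",
)

# Spellings seen in published tables and summaries that map onto the
# canonical vocabulary (abbreviated gazelles, parenthesised lion labels,
# singular 'rodent', 'bird (other)').
_ALIASES: dict[str, str] = {
    "g. gazelle": "grant's gazelle",
    "grants gazelle": "grant's gazelle",
    "t. gazelle": "thomson's gazelle",
    "thomsons gazelle": "thomson's gazelle",
    "lion (male)": "lion male",
    "lion (female&cubs)": "lion female&cub",
    "lion (female & cubs)": "lion female&cub",
    "lion female&cubs": "lion female&cub",
    "rodent": "rodents",
    "reptile": "reptiles",
    "bird (other)": "other bird",
    "batearedfox": "bat eared fox",
    "dikdik": "dik dik",
    "guineafowl": "guinea fowl",
    "koribustard": "kori bustard",
    "honeybadger": "honey badger",
    "hyenaspotted": "spotted hyena",
    "hyenastriped": "striped hyena",
    "secretarybird": "secretary bird",
    "vervetmonkey": "vervet monkey",
    "gazellegrants": "grant's gazelle",
    "gazellethomsons": "thomson's gazelle",
    "lionfemale": "lion female&cub",
    "lionmale": "lion male",
    "otherbird": "other bird",
}

_SPECIES_SET = frozenset(SPECIES)


class UnknownSpeciesError(ValueError):
    """A label does not map onto the controlled vocabulary."""


def _normalise(label: str) -> str:
    # Typographic apostrophes and stray whitespace must not create
    # duplicate vocabulary entries.
    s = label.strip().lower().replace("’", "'").replace("–", "-")
    return " ".join(s.split())


def canonical_species(
    label: str,
    *,
    allow_blank: bool = False,
    allow_impossible: bool = False,
) -> str:
    """Map ``label`` to its canonical vocabulary entry.

    Comparison is case-insensitive after trimming; typographic apostrophes
    are folded to ASCII. Reserved tokens are accepted only where the flags
    permit: volunteers may answer ``blank`` but never ``impossible``, while
    gold-standard tables may contain ``impossible``.

    Raises
    ------
    UnknownSpeciesError
        If the label is not in the vocabulary (or is a reserved token not
        permitted here).
    """
    s = _normalise(label)
    s = _ALIASES.get(s, s)
    if s == BLANK:
        if allow_blank:
            return BLANK
        raise UnknownSpeciesError("'blank' is not a species label in this context")
    if s == IMPOSSIBLE:
        if allow_impossible:
            return IMPOSSIBLE
        raise UnknownSpeciesError(
            "'impossible' is reserved for gold-standard tables"
        )
    if s not in _SPECIES_SET:
        raise UnknownSpeciesError(f"unknown species label: {label!r}")
    return s


def is_species(label: str) -> bool:
    """True if ``label`` maps to one of the 48 species options."""
    try:
        canonical_species(label)
    except UnknownSpeciesError:
        return False
    return True
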