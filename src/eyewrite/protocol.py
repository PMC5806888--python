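"""The eye-writing input protocol: characters -> strokes -> basic motions.

A protocol has three levels.  Eleven *basic motion units* are the model
atoms: nine directional gaze motions (the four cardinal and four diagonal
directions plus a return-to-center motion), a blink, and ``sil`` — the eye
resting at the neutral position.  Twelve *strokes* are reusable glyph
fragments, each a short motion sequence (stroke 12 is a single blink used
for dots and diacritic ticks).  The *lexicon* maps each of 70 Katakana
characters to a stroke sequence; derived (voiced) characters append mark
strokes to their base character.

``compile_text`` turns a character string into the motion-unit string that
the recognizer models, inserting ``sil`` according to the protocol's
``sil_policy``.  Consecutive ``sil`` units are collapsed, which makes
compilation a homomorphism over concatenation: with the between-characters
policy, ``compile(a + b) == collapse(compile(a) + [sil] + compile(b))``.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import yaml

__all__ = [
    "SIL",
    "BLINK",
    "DEFAULT_UNITS",
    "Stroke",
    "Protocol",
    "ProtocolError",
    "UnknownUnitError",
    "UnknownStrokeError",
    "OutOfVocabularyError",
    "load_protocol",
    "default_protocol",
    "validate_protocol",
]

SIL = "sil"
BLINK = "blink"

DEFAULT_UNITS = (
    "up", "down", "left", "right",
    "upper_left", "upper_right", "lower_left", "lower_right",
    "center_return", BLINK, SIL,
)


class ProtocolError(ValueError):
    pass


class UnknownUnitError(ProtocolError):
    pass


class UnknownStrokeError(ProtocolError, KeyError):
    pass


class OutOfVocabularyError(ProtocolError, KeyError):
    def __init__(self, char: str):
        super().__init__(f"character {char!r} is not in the protocol lexicon")
        self.char = char


@dataclass(frozen=True)
class Stroke:
    id: int
    motions: tuple

    def __post_init__(self) -> None:
        object.__setattr__(self, "motions", tuple(self.motions))
        if not self.motions:
            raise ProtocolError(f"stroke {self.id} has no motions")
        if SIL in self.motions:
            raise ProtocolError(f"stroke {self.id} must not contain sil")


@dataclass
class Protocol:
    """Validated three-level input protocol."""

    units: tuple = DEFAULT_UNITS
    strokes: dict = field(default_factory=dict)       # id -> Stroke
    lexicon: dict = field(default_factory=dict)       # char -> tuple of stroke ids
    romaji: dict = field(default_factory=dict)        # alias -> char
    sil_policy: str = "both"  # between_strokes | between_characters | both

    def __post_init__(self) -> None:
        self.validate()

    # -- queries ----------------------------------------------------------

    @property
    def characters(self) -> tuple:
        return tuple(self.lexicon)

    def resolve(self, symbol: str) -> str:
        """Resolve a character or romaji alias to the character symbol."""
        if symbol in self.lexicon:
            return symbol
        if symbol in self.romaji:
            return self.romaji[symbol]
        raise OutOfVocabularyError(symbol)

    def motions_of_stroke(self, stroke_id: int) -> tuple:
        try:
            return self.strokes[stroke_id].motions
        except KeyError:
            raise UnknownStrokeError(f"unknown stroke id {stroke_id}") from None

    def expand_character(self, char: str) -> tuple:
        """Motion sequence of one character (inter-stroke sil per policy,
        no leading/trailing sil)."""
        char = self.resolve(char)
        between = self.sil_policy in ("between_strokes", "both")
        out = []
        for i, sid in enumerate(self.lexicon[char]):
            if i > 0 and between:
                out.append(SIL)
            out.extend(self.motions_of_stroke(sid))
        return tuple(out)

    def compile_text(self, text) -> tuple:
        """Compile a character sequence into the full motion-unit string.

        Leading and trailing sil are always present; consecutive sil
        collapse to one.
        """
        between = self.sil_policy in ("between_characters", "both")
        out = [SIL]
        for i, char in enumerate(text):
            if i > 0 and between:
                out.append(SIL)
            out.extend(self.expand_character(char))
        out.append(SIL)
        return collapse_sil(out)

    def ambiguous_groups(self) -> list:
        """Groups of >= 2 characters whose motion expansions are identical."""
        by_expansion: dict = {}
        for char in self.lexicon:
            by_expansion.setdefault(self.expand_character(char), []).append(char)
        return [sorted(g) for g in by_expansion.values() if len(g) > 1]

    # -- validation -------------------------------------------------------

    def validate(self) -> dict:
        if len(set(self.units)) != len(self.units):
            raise ProtocolError("duplicate unit names")
        if SIL not in self.units:
            raise ProtocolError("unit inventory must contain sil")
        unit_set = set(self.units)
        for stroke in self.strokes.values():
            for m in stroke.motions:
                if m not in unit_set:
                    raise UnknownUnitError(
                        f"stroke {stroke.id} references unknown unit {m!r}")
        for char, sids in self.lexicon.items():
            if not sids:
                raise ProtocolError(f"character {char!r} has an empty expansion")
            for sid in sids:
                if sid not in self.strokes:
                    raise ProtocolError(
                        f"character {char!r} references missing stroke id {sid}")
        return {
            "n_units": len(self.units),
            "n_strokes": len(self.strokes),
            "n_characters": len(self.lexicon),
            "ambiguous": self.ambiguous_groups(),
        }

    def motion_alphabet(self) -> tuple:
        """All units reachable from the lexicon, plus sil."""
        used = {SIL}
        for char in self.lexicon:
            used.update(self.expand_character(char))
        return tuple(u for u in self.units if u in used)


def collapse_sil(motions) -> tuple:
    out = []
    for m in motions:
        if m == SIL and out and out[-1] == SIL:
            continue
        out.append(m)
    return tuple(out)


def validate_protocol(p: Protocol) -> dict:
    return p.validate()


def load_protocol(path=None) -> Protocol:
    """Load a protocol from a YAML file (default: the shipped Katakana table)."""
    if path is None:
        ref = importlib.resources.files("eyewrite") / "data" / "protocol_katakana.yaml"
        raw = yaml.safe_load(ref.read_text(encoding="utf-8"))
    else:
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
    units = tuple(raw.get("units", DEFAULT_UNITS))
    strokes = {int(k): Stroke(int(k), tuple(v)) for k, v in raw["strokes"].items()}
    marks = {k: tuple(v) for k, v in raw.get("marks", {}).items()}

    lexicon: dict = {}
    romaji: dict = {}
    deferred = []
    for char, entry in raw["characters"].items():
        char = str(char)
        if char in lexicon:
            raise ProtocolError(f"duplicate character {char!r}")
        if "strokes" in entry:
            lexicon[char] = tuple(int(s) for s in entry["strokes"])
        elif "base" in entry:
            deferred.append((char, entry))
        else:
            raise ProtocolError(f"character {char!r} has neither strokes nor base")
        if "romaji" in entry:
            romaji[str(entry["romaji"])] = char
    for char, entry in deferred:
        base = str(entry["base"])
        if base not in lexicon:
            raise ProtocolError(f"derived character {char!r} has unknown base {base!r}")
        mark = entry["mark"]
        if mark not in marks:
            raise ProtocolError(f"unknown mark {mark!r} for character {char!r}")
        if char in lexicon:
            raise ProtocolError(f"duplicate character {char!r}")
        lexicon[char] = lexicon[base] + marks[mark]

    return Protocol(units=units, strokes=strokes, lexicon=lexicon,
                    romaji=romaji, sil_policy=raw.get("sil_policy", "both"))


_DEFAULT: Protocol | None = None


def default_protocol() -> Protocol:
    """The shipped 70-character Katakana protocol (cached)."""
    global _DEFAULT
    if _DEFAULT is None:
        _DEFAULT = load_protocol()
    return _DEFAULT
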