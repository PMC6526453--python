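"""Structure of the paper-based lexical decision experiment.

The task is administered on printed pages: each session consists of a fixed
number of pages with a fixed number of letter-string stimuli per page, and
the participant ticks a "yes" (word) or "no" (nonword) checkbox per item
with a digital pen. The first item on every page cannot receive a response
time (there is no preceding pen stroke on that page to anchor it), so it is
scheduled as a *reference* stimulus and excluded from analysis; every other
item's RT is the time from the pen-up of the previous item's mark to the
pen-down of its own mark.

With the default configuration (67 sessions x 3 pages x 11 items) the
schedule holds 2211 stimuli: 201 references and 2010 analyzed items, 15
words and 15 nonwords per session.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List

import numpy as np

from ._exceptions import ConfigurationError

__all__ = [
    "ExperimentDesign",
    "StimulusSpec",
    "build_design",
    "make_nonword",
    "generate_stimulus_pool",
]

_VOWELS = "aeiou"
_UMLAUT_MAP = {"ä": "a", "ö": "o", "ü": "u"}
_CONSONANTS = "bdfgklmnprst"


@dataclass(frozen=True)
class ExperimentDesign:
    """Counts and stimulus constraints defining one experiment layout."""

    n_sessions: int = 67
    pages_per_session: int = 3
    items_per_page: int = 11
    n_practice_sessions: int = 2
    words_per_session: int = 15
    nonwords_per_session: int = 15
    word_length_min: int = 5
    word_length_max: int = 7
    low_frequency_proportion: float = 0.467

    def validate(self) -> "ExperimentDesign":
        if self.items_per_page < 2:
            raise ConfigurationError("items_per_page must be at least 2")
        per_session = self.pages_per_session * (self.items_per_page - 1)
        if self.words_per_session + self.nonwords_per_session != per_session:
            raise ConfigurationError(
                "words_per_session + nonwords_per_session must equal "
                f"pages_per_session * (items_per_page - 1) = {per_session}"
            )
        if not self.n_practice_sessions < self.n_sessions:
            raise ConfigurationError("practice sessions must be fewer than sessions")
        if not 0.0 <= self.low_frequency_proportion <= 1.0:
            raise ConfigurationError("low_frequency_proportion must be in [0, 1]")
        if not 1 <= self.word_length_min <= self.word_length_max:
            raise ConfigurationError("invalid word length range")
        return self

    @property
    def n_stimuli(self) -> int:
        return self.n_sessions * self.pages_per_session * self.items_per_page

    @property
    def n_references(self) -> int:
        return self.n_sessions * self.pages_per_session

    @property
    def n_analyzed(self) -> int:
        return self.n_stimuli - self.n_references


@dataclass(frozen=True)
class StimulusSpec:
    """One scheduled stimulus: text, condition, and its position."""

    stimulus_id: int
    text: str
    condition: str  # "word" | "nonword"
    frequency_class: str  # "low" | "very_low" | "none"
    session: int  # 1-based
    page: int  # 1-based
    slot: int  # 1-based position on the page; slot 1 is the reference
    is_reference: bool


def make_nonword(word: str, rng: np.random.Generator) -> str:
    """Derive a nonword by replacing every vowel with a different vowel.

    Consonants stay in place, so length and consonant skeleton are
    preserved. A ``u`` immediately following ``q`` is left unchanged
    (keeping strings pronounceable), and umlauts are always replaced by
    plain (non-umlaut) vowels. Vowel-free input is returned unchanged.
    """
    out = []
    prev = ""
    for ch in word:
        low = ch.lower()
        if low in _UMLAUT_MAP:
            # umlaut: any plain vowel other than its base letter
            choices = [c for c in _VOWELS if c != _UMLAUT_MAP[low]]
            rep = choices[rng.integers(len(choices))]
            out.append(rep.upper() if ch.isupper() else rep)
        elif low in _VOWELS:
            if low == "u" and prev == "q":
                out.append(ch)
            else:
                choices = [c for c in _VOWELS if c != low]
                rep = choices[rng.integers(len(choices))]
                out.append(rep.upper() if ch.isupper() else rep)
        else:
            out.append(ch)
        prev = low
    return "".join(out)


def _random_word(length: int, rng: np.random.Generator) -> str:
    """Pronounceable-looking placeholder word (alternating consonant/vowel)."""
    chars = []
    for i in range(length):
        pool = _CONSONANTS if i % 2 == 0 else _VOWELS
        chars.append(pool[rng.integers(len(pool))])
    return "".join(chars)


def generate_stimulus_pool(
    n_words: int, design: ExperimentDesign, rng: np.random.Generator
):
    """Generate ``n_words`` placeholder words and one nonword for each.

    Word lengths are uniform over the design's letter-count range. A
    fraction ``low_frequency_proportion`` of the words is labeled "low"
    frequency, the rest "very_low" (labels only; the placeholder lexicon
    carries no real frequency information). Returns ``(words, nonwords,
    frequency_classes)``.
    """
    if n_words < 1:
        raise ConfigurationError("n_words must be at least 1")
    design.validate()
    words: List[str] = []
    seen = set()
    while len(words) < n_words:
        length = int(rng.integers(design.word_length_min, design.word_length_max + 1))
        w = _random_word(length, rng)
        if w not in seen:
            seen.add(w)
            words.append(w)
    nonwords = [make_nonword(w, rng) for w in words]
    n_low = int(round(design.low_frequency_proportion * n_words))
    classes = np.array(["low"] * n_low + ["very_low"] * (n_words - n_low))
    rng.shuffle(classes)
    return words, nonwords, list(classes)


def build_design(
    config: ExperimentDesign, rng: np.random.Generator
) -> List[StimulusSpec]:
    """Build a full randomized stimulus schedule for one experiment.

    Every page gets a reference stimulus in slot 1, drawn randomly from the
    word/nonword pool; the remaining slots of each session hold exactly
    ``words_per_session`` words and ``nonwords_per_session`` nonwords in
    randomized order.
    """
    config.validate()
    n_words_needed = config.n_sessions * config.words_per_session
    n_nonwords_needed = config.n_sessions * config.nonwords_per_session
    n_refs = config.n_references
    pool_size = max(n_words_needed, n_nonwords_needed) + n_refs
    words, nonwords, classes = generate_stimulus_pool(pool_size, config, rng)

    schedule: List[StimulusSpec] = []
    word_cursor = 0
    nonword_cursor = 0
    stim_id = 0
    for session in range(1, config.n_sessions + 1):
        # the session's non-reference items, shuffled across its pages
        items = ["word"] * config.words_per_session + [
            "nonword"
        ] * config.nonwords_per_session
        items = list(np.array(items)[rng.permutation(len(items))])
        it = iter(items)
        for page in range(1, config.pages_per_session + 1):
            for slot in range(1, config.items_per_page + 1):
                if slot == 1:
                    # reference: random draw from the pooled stimuli
                    cond = "word" if rng.random() < 0.5 else "nonword"
                else:
                    cond = next(it)
                if cond == "word":
                    text = words[word_cursor % len(words)]
                    fclass = classes[word_cursor % len(words)]
                    word_cursor += 1
                else:
                    text = nonwords[nonword_cursor % len(nonwords)]
                    fclass = "none"
                    nonword_cursor += 1
                schedule.append(
                    StimulusSpec(
                        stimulus_id=stim_id,
                        text=text,
                        condition=cond,
                        frequency_class=fclass,
                        session=session,
                        page=page,
                        slot=slot,
                        is_reference=(slot == 1),
                    )
                )
                stim_id += 1
    return schedule
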