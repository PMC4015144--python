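"""Seeded generator of synthetic patent corpora and terminologies.

Real patent collections used to tune this kind of engine are proprietary, so
experiments here run on generated corpora that reproduce the statistical
structure the tuning strategies rely on:

* latent topical clusters: each patent draws its title/abstract/claims
  mostly from one topic's vocabulary, so topically related patents share
  terms;
* long, noisy descriptions: the description field is an order of magnitude
  longer than the other fields and mostly drawn from a shared noise
  vocabulary, making it cheap to match but poor at discriminating topics;
* a citation network biased toward same-topic, already-cited patents
  (preferential attachment), so citation counts correlate with prior-art
  relevance;
* IPC codes deterministic per topic, so class codes are a clean topical
  signal.

All randomness flows from one seed through named substreams, so the same
config yields byte-identical corpora.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._stopwords import DEFAULT_STOPWORDS
from .corpus import PatentCorpus, PatentDocument, Scope, Terminology, extract_field_text
from .index import tokenize

__all__ = ["SynthConfig", "generate_corpus", "generate_terminology"]

_CONSONANTS = "bcdfghjklmnpqrstvz"
_VOWELS = "aeiou"

# substream tags (second word of the default_rng seed sequence)
_S_VOCAB, _S_TEXT, _S_CITE, _S_TERM = 0, 1, 2, 10


@dataclass
class SynthConfig:
    """Parameters of the synthetic corpus.

    ``field_lengths`` are expected token counts per field; descriptions are
    diluted with ``description_noise_frac`` noise-vocabulary tokens.
    ``citation_topic_bias`` is the probability that a citation targets an
    earlier same-topic patent; targets are weighted by
    (in-degree + 1) ** preferential_attachment.
    """

    n_patents: int = 300
    n_topics: int = 10
    vocab_size_topic: int = 100
    vocab_size_noise: int = 500
    field_lengths: dict[str, int] = field(
        default_factory=lambda: {
            "title": 8,
            "abstract": 60,
            "claims": 120,
            "description": 600,
        }
    )
    vocab_overlap_frac: float = 0.3
    description_noise_frac: float = 0.8
    tac_noise_frac: float = 0.1
    citation_rate: float = 3.0
    citation_topic_bias: float = 0.9
    preferential_attachment: float = 1.0
    ipc_per_patent: int = 2
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_patents", "n_topics", "vocab_size_topic", "vocab_size_noise", "ipc_per_patent"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        for name in (
            "vocab_overlap_frac",
            "description_noise_frac",
            "tac_noise_frac",
            "citation_topic_bias",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.citation_rate < 0 or self.preferential_attachment < 0:
            raise ValueError("citation_rate and preferential_attachment must be >= 0")
        if self.n_patents < 2 and self.citation_rate > 0:
            raise ValueError("citations require at least 2 patents")
        missing = {"title", "abstract", "claims", "description"} - set(self.field_lengths)
        if missing:
            raise ValueError(f"field_lengths missing fields: {sorted(missing)}")

    @classmethod
    def from_dict(cls, data: dict) -> "SynthConfig":
        cfg = cls(**data)
        cfg.validate()
        return cfg


def _make_words(rng: np.random.Generator, count: int, taken: set[str]) -> list[str]:
    """Unique pronounceable CV-syllable words, avoiding stopwords."""
    words: list[str] = []
    while len(words) < count:
        n_syll = int(rng.integers(2, 4))
        w = "".join(
            _CONSONANTS[rng.integers(len(_CONSONANTS))] + _VOWELS[rng.integers(len(_VOWELS))]
            for _ in range(n_syll)
        )
        if w in taken or w in DEFAULT_STOPWORDS:
            continue
        taken.add(w)
        words.append(w)
    return words


def _zipf_probs(size: int) -> np.ndarray:
    weights = 1.0 / np.arange(1, size + 1)
    return weights / weights.sum()


def _ipc_codes_for_topic(topic: int, ipc_per_patent: int) -> list[str]:
    codes = []
    for j in range(ipc_per_patent):
        section = "ABCDEFGH"[(topic + j) % 8]
        cls = (topic * 7 + j * 3) % 99 + 1
        subclass = chr(ord("A") + (topic * 3 + j) % 26)
        group = topic + j + 1
        subgroup = (topic * 5 + j) % 90 + 10
        codes.append(f"{section}{cls:02d}{subclass} {group}/{subgroup}")
    return codes


def _draw_field(
    rng: np.random.Generator,
    mean_len: int,
    min_len: int,
    topic_vocab: list[str],
    topic_probs: np.ndarray,
    noise_vocab: list[str],
    noise_probs: np.ndarray,
    noise_frac: float,
) -> str:
    length = max(min_len, int(rng.poisson(mean_len)))
    noise_mask = rng.random(length) < noise_frac
    topic_idx = rng.choice(len(topic_vocab), size=length, p=topic_probs)
    noise_idx = rng.choice(len(noise_vocab), size=length, p=noise_probs)
    tokens = [
        noise_vocab[noise_idx[i]] if noise_mask[i] else topic_vocab[topic_idx[i]]
        for i in range(length)
    ]
    return " ".join(tokens)


def generate_corpus(config: SynthConfig) -> PatentCorpus:
    """Generate a corpus under ``config``; reproducible under the seed.

    Each patent cites only earlier-generated patents, so the citation graph
    is acyclic by construction.
    """
    config.validate()
    rng_vocab = np.random.default_rng([config.seed, _S_VOCAB])
    rng_text = np.random.default_rng([config.seed, _S_TEXT])
    rng_cite = np.random.default_rng([config.seed, _S_CITE])

    taken: set[str] = set()
    # Topic vocabularies overlap through a shared pool of ambiguous words:
    # real technical vocabulary ("inhibitor", "assay") spans many patent
    # classes, and that ambiguity is what class codes can resolve at query
    # time.  Each topic draws vocab_overlap_frac of its words from the pool.
    # pool sized like one topic vocabulary, so each shared word lands in a
    # few topics rather than all of them
    n_shared = int(round(config.vocab_overlap_frac * config.vocab_size_topic))
    shared_pool = _make_words(rng_vocab, config.vocab_size_topic, taken) if n_shared else []
    topic_vocabs = []
    for _ in range(config.n_topics):
        own = _make_words(rng_vocab, config.vocab_size_topic - n_shared, taken)
        shared_idx = rng_vocab.choice(len(shared_pool), size=n_shared, replace=False) if n_shared else []
        vocab = own + [shared_pool[i] for i in shared_idx]
        order = rng_vocab.permutation(len(vocab))
        topic_vocabs.append([vocab[i] for i in order])
    noise_vocab = _make_words(rng_vocab, config.vocab_size_noise, taken)
    topic_probs = _zipf_probs(config.vocab_size_topic)
    noise_probs = _zipf_probs(config.vocab_size_noise)

    topics = rng_text.integers(config.n_topics, size=config.n_patents)
    docs: list[PatentDocument] = []
    indegree = np.zeros(config.n_patents, dtype=float)
    lengths = config.field_lengths
    for i in range(config.n_patents):
        t = int(topics[i])
        vocab = topic_vocabs[t]
        fields = {}
        for name, noise_frac, min_len in (
            ("title", config.tac_noise_frac, 3),
            ("abstract", config.tac_noise_frac, 1),
            ("claims", config.tac_noise_frac, 1),
            ("description", config.description_noise_frac, 1),
        ):
            fields[name] = _draw_field(
                rng_text, lengths[name], min_len, vocab, topic_probs,
                noise_vocab, noise_probs, noise_frac,
            )
        cited: list[str] = []
        if i > 0 and config.citation_rate > 0:
            n_cite = min(int(rng_cite.poisson(config.citation_rate)), i)
            chosen: set[int] = set()
            for _ in range(n_cite):
                same_topic = [
                    j for j in range(i) if topics[j] == t and j not in chosen
                ]
                if rng_cite.random() < config.citation_topic_bias and same_topic:
                    pool = same_topic
                else:
                    pool = [j for j in range(i) if j not in chosen]
                if not pool:
                    break
                weights = (indegree[pool] + 1.0) ** config.preferential_attachment
                probs = weights / weights.sum()
                target = int(np.asarray(pool)[rng_cite.choice(len(pool), p=probs)])
                chosen.add(target)
                indegree[target] += 1.0
            cited = [f"SP{j:06d}" for j in sorted(chosen)]
        docs.append(
            PatentDocument(
                patent_id=f"SP{i:06d}",
                title=fields["title"],
                abstract=fields["abstract"],
                claims=fields["claims"],
                description=fields["description"],
                ipc_codes=_ipc_codes_for_topic(t, config.ipc_per_patent),
                cited_ids=cited,
            )
        )
    return PatentCorpus(iter(docs))


def generate_terminology(
    config: SynthConfig,
    corpus: PatentCorpus,
    n_concepts: int = 20,
    terms_per_concept: int = 2,
    name: str = "SYNTERM",
) -> Terminology:
    """Build a toy terminology over phrases present in the corpus TAC text.

    Concepts are 1-3 token phrases sampled from the corpus (so every concept
    has at least one synonym findable in some patent); extra synonyms are
    freshly generated words.  Reproducible under the config seed.
    """
    config.validate()
    if n_concepts < 1 or terms_per_concept < 1:
        raise ValueError("n_concepts and terms_per_concept must be positive")
    rng = np.random.default_rng([config.seed, _S_TERM])
    phrases: set[str] = set()
    for doc in corpus:
        tokens = tokenize(extract_field_text(doc, Scope.TAC))
        for n in (1, 2, 3):
            for i in range(len(tokens) - n + 1):
                phrases.add(" ".join(tokens[i : i + n]))
    candidates = sorted(phrases)
    if n_concepts > len(candidates):
        raise ValueError(
            f"requested {n_concepts} concepts but only {len(candidates)} distinct phrases exist"
        )
    chosen = rng.choice(len(candidates), size=n_concepts, replace=False)
    terminology = Terminology(name=name)
    taken = set(candidates)
    for idx, ci in enumerate(sorted(int(c) for c in chosen), start=1):
        concept_id = f"C{idx:05d}"
        terminology.add_term(candidates[ci], name, concept_id)
        extra = _make_words(rng, terms_per_concept - 1, taken)
        for syn in extra:
            terminology.add_term(syn, name, concept_id)
    return terminology
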