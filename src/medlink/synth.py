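"""Self-contained synthetic fixtures with controlled cross-group ambiguity.

Real corpora for broad-coverage entity linking are licensed and large; the
generators here reproduce the *structure* that matters to this package so
every stage is exercisable offline:

* an inventory whose surface forms are shared across concepts of different
  semantic groups at a configurable rate (the "cold" situation: one string,
  several concepts, several groups);
* corpora whose mention contexts carry a group-specific cue token with
  configurable reliability, making the learnability ceiling analytic —
  ``cue_strength=1`` means the context determines the group exactly, and
  ``cue_strength = 1/n_groups`` means the context is uninformative;
* MeSH-headed documents where an exactly configurable fraction of gold
  mentions match a header, pinning the expected precision/recall of the
  distant-supervision annotator by construction.

Everything is a pure function of (config, seed).  Cue tokens and filler
words are nonsense strings disjoint from mention surfaces, so no mention
ambiguity leaks into the context signal.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from random import Random

from .corpus_io import (
    AnnotatedCorpus,
    CandidateList,
    ConceptEntry,
    ConceptInventory,
    Document,
    Mention,
)
from .errors import ConfigError
from .linking import Lexicon, build_lexicon, generate_candidates
from .typescheme import TypeScheme, load_scheme
from .weaksup import CrosswalkEntry, MeshCrosswalk

_FILLERS = ("alpha", "beta", "gamma", "delta", "epsilon", "zeta", "eta", "theta")


@dataclass(frozen=True)
class SynthConfig:
    """Generation parameters; defaults are the package's study conditions."""

    seed: int = 0
    n_concepts: int = 60
    n_groups_used: int = 6
    ambiguity_rate: float = 0.5  # fraction of surface forms shared across groups
    n_docs: int = 120
    mentions_per_doc: int = 4
    cue_strength: float = 1.0  # P(correct group cue appears next to a mention)
    candidate_noise: int = 1  # extra spurious candidates appended per mention
    linkable_fraction: float = 0.2  # mesh fixture: fraction of gold mentions
    multi_type_rate: float = 0.2  # P(concept gets a 2nd fine type, same group)

    def __post_init__(self) -> None:
        for name in ("ambiguity_rate", "cue_strength", "linkable_fraction", "multi_type_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        for name in ("n_concepts", "n_docs", "mentions_per_doc"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be positive")
        if not 1 <= self.n_groups_used <= 24:
            raise ConfigError(f"n_groups_used must be in [1, 24], got {self.n_groups_used}")
        if self.ambiguity_rate > 0 and self.n_groups_used < 2:
            raise ConfigError("cross-group ambiguity needs n_groups_used >= 2")
        if self.candidate_noise < 0:
            raise ConfigError("candidate_noise must be >= 0")


def _groups_used(cfg: SynthConfig, scheme: TypeScheme) -> list[str]:
    rng = Random(f"{cfg.seed}:groups")
    return rng.sample(list(scheme.group_names), cfg.n_groups_used)


def cue_token(group_index: int) -> str:
    return f"cueword{group_index:02d}"


def _inventory_cues(
    inventory: ConceptInventory, scheme: TypeScheme
) -> dict[str, str]:
    """Cue word per group actually present in the inventory.

    Indexed by the group's position in the scheme so the same group always
    gets the same cue word regardless of generator configuration.
    """
    present = sorted(
        {
            g
            for cui in inventory.entries
            for g in scheme.groups_of_concept(inventory[cui].fine_types)
        }
    )
    return {g: cue_token(scheme.group_names.index(g)) for g in present}


def make_inventory(cfg: SynthConfig, scheme: TypeScheme | None = None) -> ConceptInventory:
    """Concepts round-robin over the used groups, with shared surface forms.

    ``round(ambiguity_rate * n_concepts)`` of the ``n_concepts`` surface
    forms are assigned as names to two concepts of different groups (the
    round-robin makes consecutive concepts differ in group); the rest are
    unique.  Unique forms are dealt first so low-index concepts keep
    unambiguous preferred names — useful for fixtures that need them.
    """
    scheme = scheme or load_scheme()
    rng = Random(f"{cfg.seed}:inventory")
    groups = _groups_used(cfg, scheme)
    types_by_group = {g: sorted(t for t, gg in scheme.entries.items() if gg == g) for g in groups}

    n = cfg.n_concepts
    concept_group = [groups[i % len(groups)] for i in range(n)]
    concept_types: list[set[str]] = []
    for i in range(n):
        pool = types_by_group[concept_group[i]]
        types = {rng.choice(pool)}
        if len(pool) > 1 and rng.random() < cfg.multi_type_rate:
            types.add(rng.choice([t for t in pool if t not in types]))
        concept_types.append(types)

    n_amb = round(cfg.ambiguity_rate * n)
    forms = [f"term{j:04d}" for j in range(n)]
    concept_forms: list[list[str]] = [[] for _ in range(n)]
    cursor = 0
    for j, form in enumerate(forms):
        if j < n - n_amb:  # unique form
            concept_forms[cursor % n].append(form)
            cursor += 1
        else:  # shared by two consecutive concepts (different groups)
            concept_forms[cursor % n].append(form)
            concept_forms[(cursor + 1) % n].append(form)
            cursor += 2

    entries = []
    for i in range(n):
        fs = concept_forms[i]
        entries.append(
            ConceptEntry(
                cui=f"C{1000000 + i}",
                preferred_name=fs[0],
                synonyms=tuple(fs[1:]),
                fine_types=frozenset(concept_types[i]),
            )
        )
    return ConceptInventory.from_entries(entries)


def _concept_group(entry: ConceptEntry, scheme: TypeScheme) -> str:
    groups = scheme.groups_of_concept(entry.fine_types)
    assert len(groups) == 1, "synthetic concepts are single-group by construction"
    return next(iter(groups))


def _build_document(
    doc_id: str,
    title: str,
    picks: list[tuple[ConceptEntry, str, str]],  # (concept, surface, cue word)
    rng: Random,
) -> tuple[Document, list[Mention]]:
    """Lay out ``filler cue SURFACE filler`` runs and track char offsets."""
    tokens: list[str] = []
    spans: list[tuple[int, int, ConceptEntry, str]] = []  # token index of surface
    for concept, surface, cue in picks:
        tokens.append(rng.choice(_FILLERS))
        tokens.append(cue)
        spans.append((len(tokens), len(tokens) + 1, concept, surface))
        tokens.append(surface)
        tokens.append(rng.choice(_FILLERS))
    abstract = " ".join(tokens)
    doc = Document(doc_id=doc_id, title=title, abstract=abstract)
    offset_of: list[int] = []
    pos = 0
    for t in tokens:
        offset_of.append(pos)
        pos += len(t) + 1
    base = len(title) + 1
    mentions = []
    for tok_i, _, concept, surface in spans:
        start = base + offset_of[tok_i]
        mentions.append(
            Mention(
                doc_id=doc_id,
                start=start,
                end=start + len(surface),
                surface=surface,
                gold_cui=concept.cui,
            )
        )
    return doc, mentions


def make_corpus(
    inventory: ConceptInventory,
    cfg: SynthConfig,
    scheme: TypeScheme | None = None,
) -> AnnotatedCorpus:
    """Documents whose mentions carry gold CUIs and cue-bearing contexts.

    Each mention is a uniformly drawn concept rendered as one of its surface
    forms; the token just before it is its group's cue with probability
    ``cue_strength``, else a uniformly drawn *other* group's cue.
    """
    scheme = scheme or load_scheme()
    rng = Random(f"{cfg.seed}:corpus")
    cue_of = _inventory_cues(inventory, scheme)
    groups = sorted(cue_of)
    cuis = list(inventory.entries)

    documents: list[Document] = []
    mentions: list[Mention] = []
    for d in range(cfg.n_docs):
        picks = []
        for _ in range(cfg.mentions_per_doc):
            concept = inventory[rng.choice(cuis)]
            surface = rng.choice(concept.all_names)
            group = _concept_group(concept, scheme)
            if rng.random() < cfg.cue_strength:
                cue = cue_of[group]
            else:
                cue = cue_of[rng.choice([g for g in groups if g != group])]
            picks.append((concept, surface, cue))
        doc, ms = _build_document(f"D{d:05d}", f"Synthetic record {d}.", picks, rng)
        documents.append(doc)
        for m in ms:
            groups_m = scheme.groups_of_concept(inventory[m.gold_cui].fine_types)
            mentions.append(replace(m, gold_groups=groups_m))
    return AnnotatedCorpus(tuple(documents), tuple(mentions))


def make_candidates(
    corpus: AnnotatedCorpus,
    inventory: ConceptInventory,
    cfg: SynthConfig,
    lexicon: Lexicon | None = None,
    max_candidates: int = 5,
) -> dict[tuple[str, int, int], CandidateList]:
    """Lexicon candidates per mention plus ``candidate_noise`` spurious ones.

    Noise candidates are drawn from concepts not already listed and appended
    with strictly lower scores, emulating over-generation beyond exact
    lexical match.
    """
    rng = Random(f"{cfg.seed}:candidates")
    lexicon = lexicon or build_lexicon(inventory)
    cuis = list(inventory.entries)
    out: dict[tuple[str, int, int], CandidateList] = {}
    for m in corpus.mentions:
        base = generate_candidates(m, lexicon, max_candidates)
        cands = list(base.candidates)
        floor = min((s for _, s in cands), default=1.0)
        present = {c for c, _ in cands}
        for k in range(cfg.candidate_noise):
            pool = [c for c in cuis if c not in present]
            if not pool:
                break
            noise = rng.choice(pool)
            present.add(noise)
            cands.append((noise, floor * 0.5 ** (k + 1)))
        out[m.span_key] = CandidateList(
            mention=m, candidates=tuple(cands), provenance="dictionary+noise"
        )
    return out


@dataclass(frozen=True)
class MeshFixture:
    """Inputs and references for exercising the distant-supervision annotator."""

    documents: tuple[Document, ...]  # carry mesh_headers
    detected: tuple[Mention, ...]  # spans only, no gold links
    gold: AnnotatedCorpus
    crosswalk: MeshCrosswalk


def make_mesh_corpus(
    inventory: ConceptInventory,
    cfg: SynthConfig,
    scheme: TypeScheme | None = None,
) -> MeshFixture:
    """MeSH-headed documents with an exact fraction of linkable mentions.

    Mentions use only concepts whose preferred name is unambiguous (maps to
    a single concept) and are distinct within a document; exactly
    ``round(linkable_fraction * n_mentions)`` mentions get their surface
    added to their document's headers, so the weak annotator's recall equals
    that fraction and its precision is 1 by construction.
    """
    scheme = scheme or load_scheme()
    rng = Random(f"{cfg.seed}:mesh")
    name_count: dict[str, int] = {}
    for cui in inventory.entries:
        for nm in inventory[cui].all_names:
            name_count[nm] = name_count.get(nm, 0) + 1
    safe = [
        inventory[cui]
        for cui in inventory.entries
        if name_count[inventory[cui].preferred_name] == 1
    ]
    if len(safe) < cfg.mentions_per_doc:
        raise ConfigError(
            f"need >= {cfg.mentions_per_doc} concepts with unambiguous preferred "
            f"names, have {len(safe)} (lower ambiguity_rate or mentions_per_doc)"
        )
    cue_of = _inventory_cues(inventory, scheme)

    total = cfg.n_docs * cfg.mentions_per_doc
    linkable_idx = set(rng.sample(range(total), round(cfg.linkable_fraction * total)))

    documents: list[Document] = []
    gold_mentions: list[Mention] = []
    detected: list[Mention] = []
    xwalk_entries: dict[str, CrosswalkEntry] = {}
    idx = 0
    for d in range(cfg.n_docs):
        concepts = rng.sample(safe, cfg.mentions_per_doc)
        picks = []
        headers = []
        doc_linkable = []
        for concept in concepts:
            group = _concept_group(concept, scheme)
            picks.append((concept, concept.preferred_name, cue_of[group]))
            if idx in linkable_idx:
                header = concept.preferred_name.capitalize()
                headers.append(header)
                doc_linkable.append(concept)
                if concept.preferred_name not in xwalk_entries:
                    xwalk_entries[concept.preferred_name] = CrosswalkEntry(
                        header=header,
                        mesh_id=f"M{concept.cui[1:]}",
                        cui=concept.cui,
                        fine_types=concept.fine_types,
                    )
            idx += 1
        doc, ms = _build_document(f"M{d:05d}", f"Indexed record {d}.", picks, rng)
        doc = replace(doc, mesh_headers=tuple(headers))
        documents.append(doc)
        for m in ms:
            groups_m = scheme.groups_of_concept(inventory[m.gold_cui].fine_types)
            gold_mentions.append(replace(m, gold_groups=groups_m))
            detected.append(replace(m, gold_cui=None, gold_groups=None))
    gold = AnnotatedCorpus(tuple(documents), tuple(gold_mentions))
    crosswalk = MeshCrosswalk.from_entries(list(xwalk_entries.values()))
    return MeshFixture(
        documents=tuple(documents),
        detected=tuple(detected),
        gold=gold,
        crosswalk=crosswalk,
    )
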