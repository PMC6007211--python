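"""Deterministic rule-based dependency parsing for abstract sentences.

The parser targets the declarative results-sentence register of biomedical
abstracts: a (possibly fronted) prepositional or comparative phrase, a subject
noun-phrase chain, one finite predicate (copular or lexical), and a tail of
prepositional phrases. It produces *enhanced* dependencies directly:
prepositions are collapsed into ``nmod:<prep>`` labels, entity-separator
phrases ("compared to X", fronted "In comparison to X, ...") yield the
dedicated ``nmod:es`` label, and conjunct propagation copies a coordination
head's incoming relations onto every conjunct.

It is intentionally shallow — clauses joined by semicolons are parsed
independently and linked by ``parataxis``, so comparisons whose two compared
entities sit in different clauses are (by design) not connected; relative
clauses and other embeddings receive best-effort flat attachments. Parsing
never raises on odd input; unattachable tokens hang off the root as ``dep``.
"""

from __future__ import annotations

from ..lexicon import TriggerLexicons
from .graph import DepEdge, DepGraph, DepNode
from .lextag import Token

#: dialect label map -> canonical label set used throughout this package
LABEL_ALIASES = {
    "nsubjpass": "nsubj:pass",
    "dobj": "obj",
    "prep_of": "nmod:of",
    "prep_in": "nmod:in",
    "prep_with": "nmod:with",
}

_NOUNISH = {"NN", "NNS", "NNP"}
_NP_TOKEN = {"DT", "JJ", "JJR", "VBN", "CD", "NN", "NNS", "NNP"}


def canonical_label(label: str) -> str:
    return LABEL_ALIASES.get(label, label)


class Parser:
    """Adapter producing canonical enhanced dependency graphs."""

    def __init__(self, lexicons: TriggerLexicons):
        self.lexicons = lexicons
        # entity-separator phrases as lowercase surface-token tuples, longest first
        self._es_phrases = sorted(
            (tuple(p.split()) for p in lexicons.separators), key=len, reverse=True
        )

    # ------------------------------------------------------------------ API
    def parse(self, tokens: list[Token]) -> DepGraph:
        nodes = [DepNode(i, t.surface, t.lemma, t.pos) for i, t in enumerate(tokens)]
        n = len(nodes)
        if n == 0:
            return DepGraph(nodes=[], edges=[], root=0)
        edges: list[DepEdge] = []
        attached: set[int] = set()

        es_tokens = self._mark_es(tokens)
        excluded = self._mark_parentheticals(tokens) | self._mark_section_label(tokens)

        def add(gov: int, dep: int, label: str) -> None:
            if gov == dep or dep in attached:
                return
            edges.append(DepEdge(gov, dep, canonical_label(label)))
            attached.add(dep)

        clause_roots: list[int] = []
        for lo, hi in self._clauses(tokens, excluded):
            r = self._parse_clause(tokens, lo, hi, es_tokens, excluded, add)
            if r is not None:
                clause_roots.append(r)

        root = clause_roots[0] if clause_roots else 0
        graph = DepGraph(nodes=nodes, edges=edges, root=root)
        for r in clause_roots[1:]:
            if r != root and not graph.in_edges(r):
                graph.add_edge(root, r, "parataxis")
        for i in range(n):
            if i != root and not graph.in_edges(i):
                label = "punct" if tokens[i].pos == "PUNCT" else "dep"
                graph.add_edge(root, i, label)
        self._propagate_conjuncts(graph)
        return graph

    # ------------------------------------------------------------- marking
    def _mark_es(self, tokens: list[Token]) -> dict[int, int]:
        """token index -> index of last token of the ES phrase it starts."""
        surfaces = [t.surface.lower() for t in tokens]
        marks: dict[int, int] = {}
        i = 0
        while i < len(tokens):
            hit = None
            for phrase in self._es_phrases:
                if tuple(surfaces[i : i + len(phrase)]) == phrase:
                    hit = i + len(phrase) - 1
                    break
            if hit is not None:
                marks[i] = hit
                i = hit + 1
            else:
                i += 1
        return marks

    @staticmethod
    def _mark_parentheticals(tokens: list[Token]) -> set[int]:
        """Indices of non-inline parenthetical tokens (excluded from parsing).

        A single entity-like token in parens is an inline abbreviation and is
        kept; anything longer (statistics, asides) is set aside.
        """
        excluded: set[int] = set()
        i = 0
        while i < len(tokens):
            if tokens[i].surface == "(":
                j = i + 1
                while j < len(tokens) and tokens[j].surface != ")":
                    j += 1
                inner = tokens[i + 1 : j]
                inline = len(inner) == 1 and inner[0].pos in _NOUNISH
                if not inline:
                    excluded.update(range(i, min(j + 1, len(tokens))))
                i = j + 1
            else:
                i += 1
        return excluded

    @staticmethod
    def _mark_section_label(tokens: list[Token]) -> set[int]:
        """Structured-abstract label prefix ("METHODS:") at sentence start."""
        if (
            len(tokens) >= 2
            and tokens[1].surface == ":"
            and tokens[0].surface.isupper()
            and tokens[0].surface.isalpha()
        ):
            return {0, 1}
        return set()

    @staticmethod
    def _clauses(tokens: list[Token], excluded: set[int]) -> list[tuple[int, int]]:
        bounds: list[tuple[int, int]] = []
        lo = 0
        for i, t in enumerate(tokens):
            if t.surface == ";" and i not in excluded:
                bounds.append((lo, i))
                lo = i + 1
        bounds.append((lo, len(tokens)))
        return [(a, b) for a, b in bounds if b > a]

    # ------------------------------------------------------------ chunking
    def _chunk_np(self, tokens, i, hi, es_tokens, excluded, add):
        """Chunk one NP starting at ``i``; returns (head, next_index) or None.

        Head of a coordinated NP is the first conjunct's head (UD convention),
        with ``conj``/``cc`` edges to the rest — but only when the token before
        the conjunction is itself nounish (entity coordination); otherwise the
        conjunction coordinates modifiers and the run keeps one head at the end.
        """
        n = len(tokens)

        def np_tok(j: int) -> bool:
            if j >= hi or j in excluded or j in es_tokens:
                return False
            t = tokens[j]
            if t.pos in _NP_TOKEN:
                return True
            if t.surface in {"(", ")"} and j not in excluded:
                return True
            if t.pos == "RB" and j + 1 < hi and tokens[j + 1].pos in {"JJ", "JJR", "VBN"}:
                return True
            if t.pos == "CC":
                k = j + 1
                return k < hi and k not in es_tokens and k not in excluded and tokens[k].pos in _NP_TOKEN
            if t.surface == "," and j > i:
                # list coordination "X, Y and Z": the comma joins the run only
                # if NP material continues up to a conjunction
                k = j + 1
                while k < hi and k not in excluded and tokens[k].pos in _NP_TOKEN:
                    k += 1
                return (
                    k < hi
                    and k > j + 1
                    and tokens[k].pos == "CC"
                    and k + 1 < hi
                    and tokens[k + 1].pos in _NP_TOKEN
                )
            return False

        if i >= hi or i in excluded or i in es_tokens:
            return None
        if tokens[i].pos == "PRP" or tokens[i].lemma in {"that", "those"} and tokens[i].pos != "DT":
            # pronoun: single-token NP (a "that" before a noun was tagged DT)
            if tokens[i].pos == "PRP":
                return i, i + 1
        if not np_tok(i):
            return None
        j = i
        run: list[int] = []
        while j < hi and np_tok(j):
            run.append(j)
            j += 1
        # trim trailing '(' or CC that opened nothing
        while run and (tokens[run[-1]].surface == "(" or tokens[run[-1]].pos == "CC"):
            run.pop()
            j = run[-1] + 1 if run else i
        if not run:
            return None

        # split into conjunct segments at entity-coordinating CCs
        segments: list[list[int]] = [[]]
        cc_positions: list[int] = []
        comma_positions: list[int] = []
        for k in run:
            boundary = tokens[k].pos == "CC" or tokens[k].surface == ","
            if boundary and segments[-1] and tokens[segments[-1][-1]].pos in _NOUNISH | {"CD"}:
                if tokens[k].pos == "CC":
                    cc_positions.append(k)
                else:
                    comma_positions.append(k)
                segments.append([])
            else:
                segments[-1].append(k)
        segments = [s for s in segments if s]
        if len(segments) == 1:
            cc_positions = []

        def seg_head(seg: list[int]) -> int:
            for k in reversed(seg):
                if tokens[k].pos in _NOUNISH:
                    return k
            for k in reversed(seg):
                if tokens[k].pos == "CD":
                    return k
            return seg[-1]

        heads = [seg_head(s) for s in segments]
        head = heads[0]
        for seg, h in zip(segments, heads):
            self._np_internal(tokens, seg, h, add)
        for h2 in heads[1:]:
            add(head, h2, "conj")
        for k in cc_positions:
            add(head, k, "cc")
        for k in comma_positions:
            add(head, k, "punct")
        return head, j

    @staticmethod
    def _np_internal(tokens, seg, head, add) -> None:
        paren_stack: list[int] = []
        for k in seg:
            if k == head:
                continue
            t = tokens[k]
            if t.surface == "(":
                paren_stack.append(k)
                continue
            if t.surface == ")":
                continue
            if t.pos == "DT":
                add(head, k, "det")
            elif t.pos in {"JJ", "JJR", "VBN"}:
                add(head, k, "amod")
            elif t.pos == "CD":
                add(head, k, "nummod")
            elif t.pos == "RB":
                # adverb inside NP modifies the following adjective/participle
                tgt = k + 1 if k + 1 in seg else head
                add(tgt, k, "advmod")
            elif t.pos == "CC":
                add(head, k, "cc")  # modifier coordination inside one NP
            elif t.pos in _NOUNISH:
                if paren_stack:
                    add(head, k, "appos")  # inline abbreviation
                    add(k, paren_stack.pop(), "punct")
                    if k + 1 in seg and tokens[k + 1].surface == ")":
                        add(k, k + 1, "punct")
                else:
                    add(head, k, "compound")

    # ------------------------------------------------------- clause parsing
    def _parse_clause(self, tokens, lo, hi, es_tokens, excluded, add):
        i = lo
        # leading adverb(ial) + comma: "Conversely, ..."
        while i < hi and (tokens[i].pos == "RB" or tokens[i].surface == ",") and i not in excluded:
            i += 1
        fronted: list[tuple[str, int, list[int]]] = []  # (label, np_head, marker tokens)
        # fronted ES phrase or PP, terminated by a comma
        while i < hi:
            if i in excluded:
                i += 1
                continue
            if i in es_tokens:
                end = es_tokens[i]
                markers = list(range(i, end + 1))
                res = self._chunk_np(tokens, end + 1, hi, es_tokens, excluded, add)
                if res is None:
                    i = end + 1
                    break
                h, nxt = res
                fronted.append(("nmod:es", h, markers))
                i = nxt
                if i < hi and tokens[i].surface == ",":
                    i += 1
                continue
            if tokens[i].pos == "IN":
                res = self._chunk_np(tokens, i + 1, hi, es_tokens, excluded, add)
                if res is None:
                    break
                h, nxt = res
                fronted.append((f"nmod:{tokens[i].lemma}", h, [i]))
                i = nxt
                if i < hi and tokens[i].surface == ",":
                    i += 1
                continue
            break

        # ---- locate predicate
        pred, passive, cop_idx, subj_stop = self._find_predicate(tokens, i, hi, es_tokens, excluded)
        if pred is None:
            res = self._chunk_np(tokens, i, hi, es_tokens, excluded, add)
            if res is None:
                return None
            head, nxt = res
            self._attach_fronted(fronted, head, add)
            self._pp_chain(tokens, nxt, hi, head, head, es_tokens, excluded, add)
            return head

        post_start = pred + 1
        if pred < 0:
            # predicate nominal: the copular complement NP head becomes the root
            pos = -pred - 1
            res = self._chunk_np(tokens, pos, hi, es_tokens, excluded, add)
            if res is None:
                return None
            pred, post_start = res
            passive = False

        # ---- subject region: NP (PP NP)* chain
        subj = self._subject_chain(tokens, i, subj_stop, es_tokens, excluded, add)
        if subj is not None and subj != pred:
            add(pred, subj, "nsubj:pass" if passive else "nsubj")
        if cop_idx is not None:
            add(pred, cop_idx, "cop")
            for k in range(cop_idx + 1, pred if pred > cop_idx else cop_idx):
                if tokens[k].pos == "RB" and k not in excluded:
                    add(pred, k, "advmod")
        self._attach_fronted(fronted, pred, add)

        # ---- post-predicate region
        self._post_region(tokens, post_start, hi, pred, es_tokens, excluded, add)
        return pred

    @staticmethod
    def _attach_fronted(fronted, pred, add) -> None:
        for label, h, markers in fronted:
            add(pred, h, label)
            for m in markers:
                add(h, m, "mark" if label == "nmod:es" else "case")

    def _find_predicate(self, tokens, i, hi, es_tokens, excluded):
        """Returns (pred_head, passive, copula_index, subject_region_end)."""
        j = i
        while j < hi:
            if j in excluded or j in es_tokens:
                j += 1
                continue
            t = tokens[j]
            if t.lemma == "be" and t.pos in {"VBD", "VBZ", "VBP"}:
                k = j + 1
                while k < hi and (tokens[k].pos == "RB" or k in excluded):
                    k += 1
                if k < hi and tokens[k].pos == "VBN":
                    return k, True, j, j
                if k < hi and tokens[k].pos in {"JJ", "JJR"} and not self._prenominal(tokens, k, hi):
                    return k, False, j, j
                if k < hi and tokens[k].pos == "TO" and k + 1 < hi and tokens[k + 1].pos.startswith("VB"):
                    return k + 1, False, j, j
                if k < hi and (tokens[k].pos in _NP_TOKEN or tokens[k].pos == "CD"):
                    # predicate nominal: root at the complement NP head (resolved later)
                    return -(k + 1), False, j, j  # negative sentinel carries position
                return k if k < hi else j, False, j, j
            if t.lemma in {"have"} and t.pos in {"VBD", "VBZ", "VBP"}:
                k = j + 1
                while k < hi and tokens[k].pos == "RB":
                    k += 1
                if k < hi and tokens[k].pos == "VBN":
                    return k, False, j, j
                return None, False, None, j
            if t.pos in {"VBD", "VBZ", "VBP"}:
                # ambiguous participle-modifiers were already retagged VBN
                return j, False, None, j
            if t.pos == "VB" and (j == i or tokens[j - 1].pos not in {"TO", "MD"}):
                return j, False, None, j  # base-form finite verb (plural subject)
            j += 1
        return None, False, None, hi

    @staticmethod
    def _prenominal(tokens, j, hi) -> bool:
        """A JJ/JJR/VBN that still modifies a following noun is not a predicate."""
        k = j + 1
        while k < hi and tokens[k].pos in {"RB", "JJ", "JJR", "VBN"}:
            k += 1
        return k < hi and tokens[k].pos in _NOUNISH

    def _subject_chain(self, tokens, i, stop, es_tokens, excluded, add):
        res = self._chunk_np(tokens, i, stop, es_tokens, excluded, add)
        if res is None:
            # tolerate stray leading material
            j = i + 1
            while j < stop and res is None:
                res = self._chunk_np(tokens, j, stop, es_tokens, excluded, add)
                j += 1
            if res is None:
                return None
        subj, nxt = res
        self._pp_chain(tokens, nxt, stop, subj, subj, es_tokens, excluded, add)
        return subj

    def _pp_chain(self, tokens, i, hi, chain_initial, prev_head, es_tokens, excluded, add):
        """PP chain inside a nominal region: of/with attach locally, rest high."""
        while i < hi:
            if i in excluded or tokens[i].surface == ",":
                i += 1
                continue
            t = tokens[i]
            if t.pos == "IN" and i not in es_tokens:
                res = self._chunk_np(tokens, i + 1, hi, es_tokens, excluded, add)
                if res is None:
                    i += 1
                    continue
                h, nxt = res
                site = prev_head if t.lemma in {"of", "with"} else chain_initial
                add(site, h, f"nmod:{t.lemma}")
                add(h, i, "case")
                prev_head = h
                i = nxt
                continue
            if t.pos == "VBN":  # reduced relative: "... established in 1989"
                add(prev_head, i, "acl")
                prev_head = i
                chain_initial = i
                i += 1
                continue
            i += 1
        return prev_head

    def _post_region(self, tokens, i, hi, pred, es_tokens, excluded, add):
        if pred < 0:  # predicate-nominal sentinel from _find_predicate
            return
        attach_site = pred
        last_np: int | None = None
        have_obj = False
        pending_es = False
        pred_is_verb = tokens[pred].pos.startswith("VB")
        while i < hi:
            if i in excluded:
                i += 1
                continue
            t = tokens[i]
            if t.surface in {",", ".", ":"}:
                add(pred, i, "punct")
                i += 1
                continue
            if t.pos == "RB":
                add(attach_site, i, "advmod")
                i += 1
                continue
            if i in es_tokens:
                end = es_tokens[i]
                markers = list(range(i, end + 1))
                i = end + 1
                # "than in X" -> nmod:in with ES verified at the surface level;
                # "compared to X" / "than that" -> nmod:es on the bare NP
                if i < hi and tokens[i].pos == "IN" and tokens[i].lemma == "in" and i not in es_tokens:
                    res = self._chunk_np(tokens, i + 1, hi, es_tokens, excluded, add)
                    if res is not None:
                        h, nxt = res
                        add(pred, h, "nmod:in")
                        for m in markers:
                            add(h, m, "mark")
                        add(h, i, "case")
                        last_np = h
                        i = nxt
                        continue
                    i += 1
                    continue
                res = self._chunk_np(tokens, i, hi, es_tokens, excluded, add)
                if res is not None:
                    h, nxt = res
                    add(pred, h, "nmod:es")
                    for m in markers:
                        add(h, m, "mark")
                    last_np = h
                    i = nxt
                    continue
                pending_es = True
                continue
            if t.pos == "PRP" or (t.lemma in {"that", "those"} and t.pos not in {"DT", "IN"}):
                add(pred, i, "nmod:es" if pending_es else "obj")
                pending_es = False
                last_np = i
                i += 1
                continue
            if t.pos == "IN":
                prep = t.lemma
                res = self._chunk_np(tokens, i + 1, hi, es_tokens, excluded, add)
                if res is None:
                    i += 1
                    continue
                h, nxt = res
                if prep in {"of", "with"} and last_np is not None:
                    site = last_np
                elif prep == "in" and last_np is not None and tokens[last_np].pos == "PRP" or (
                    prep == "in" and last_np is not None and tokens[last_np].lemma in {"that", "those"}
                ):
                    site = last_np
                else:
                    site = attach_site
                add(site, h, f"nmod:{prep}")
                add(h, i, "case")
                last_np = h
                i = nxt
                continue
            if t.pos == "TO" and i + 1 < hi and tokens[i + 1].pos.startswith("VB"):
                add(pred, i + 1, "xcomp")
                add(i + 1, i, "mark")
                attach_site = i + 1
                i += 2
                continue
            if t.pos in {"VBG", "VBN"} and i not in es_tokens:
                add(attach_site, i, "advcl")
                attach_site = i
                i += 1
                continue
            res = self._chunk_np(tokens, i, hi, es_tokens, excluded, add)
            if res is not None:
                h, nxt = res
                if pending_es:
                    add(pred, h, "nmod:es")
                    pending_es = False
                elif pred_is_verb and not have_obj and attach_site == pred:
                    add(pred, h, "obj")
                    have_obj = True
                else:
                    add(attach_site, h, "dep")
                last_np = h
                i = nxt
                continue
            i += 1

    # --------------------------------------------------------- enhancement
    @staticmethod
    def _propagate_conjuncts(graph: DepGraph) -> None:
        """Copy a coordination head's incoming relations onto each conjunct."""
        for e in list(graph.edges):
            if e.label != "conj":
                continue
            for incoming in list(graph.in_edges(e.governor)):
                if incoming.label in {"conj", "cc", "punct"}:
                    continue
                graph.add_edge(incoming.governor, e.dependent, incoming.label, propagated=True)
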