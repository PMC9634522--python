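import numpy as np
import pytest

from biorel.parses import SentenceGraph, Token
from biorel.standoff import Document, Entity, RelationAnnotation
from biorel.task import load_task


def make_sentence(words, edges, pos=None, offset=0):
    """Build a SentenceGraph from words and (head, dep, label) edges."""
    tokens = []
    o = offset
    for i, w in enumerate(words):
        tokens.append(Token(w, (pos or ["NN"] * len(words))[i], o, o + len(w)))
        o += len(w) + 1
    sg = SentenceGraph(tokens=tokens, edges=list(edges))
    sg.validate()
    return sg


@pytest.fixture(scope="session")
def bbrel():
    return load_task("bbrel")


@pytest.fixture
def microbe_phenotype_doc():
    """The canonical dependency-graph fixture: a microorganism entity and a
    phenotype entity joined by the path nsubj / prep_of / amod, plus
    det/cop/advmod attachments off the path."""
    words = ["Enterococcus", "is", "a", "cause", "of", "Gram-positive", "infection"]
    edges = [
        (3, 0, "nsubj"),
        (3, 1, "cop"),
        (3, 2, "det"),
        (3, 4, "advmod"),
        (3, 6, "prep_of"),
        (6, 5, "amod"),
    ]
    sent = make_sentence(words, edges)
    text = " ".join(words) + "\n"
    t0, t5 = sent.tokens[0], sent.tokens[5]
    e1 = Entity("T1", "Microorganism", t0.char_start, t0.char_end, t0.word)
    e2 = Entity("T2", "Phenotype", t5.char_start, t5.char_end, t5.word)
    doc = Document(doc_id="demo", text=text, entities=[e1, e2])
    from biorel.parses import attach_parses

    attach_parses(doc, [sent])
    return doc


def random_connected_graph(rng, n):
    """Random spanning tree plus a few extra labelled edges."""
    edges = []
    labels = ["nsubj", "dobj", "amod", "det", "prep_of", "nmod"]
    for i in range(1, n):
        h = int(rng.integers(0, i))
        edges.append((h, i, labels[int(rng.integers(len(labels)))]))
    for _ in range(int(rng.integers(0, max(1, n // 3)))):
        a, b = rng.integers(0, n, size=2)
        if a != b:
            edges.append((int(a), int(b), labels[int(rng.integers(len(labels)))]))
    words = [f"w{i}" for i in range(n)]
    return make_sentence(words, edges)


def bfs_distance(sent, a, b):
    adj = {i: set() for i in range(len(sent.tokens))}
    for h, d, _l in sent.edges:
        adj[h].add(d)
        adj[d].add(h)
    dist = {a: 0}
    frontier = [a]
    while frontier:
        nxt = []
        for u in frontier:
            for v in adj[u]:
                if v not in dist:
                    dist[v] = dist[u] + 1
                    nxt.append(v)
        frontier = nxt
    return dist.get(b)
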