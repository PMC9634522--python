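"""Extract and orient the shortest dependency path between two entities.

Builds the sentence "Enterococcus is a cause of Gram-positive infection"
with its dependency parse, converts the parse to an undirected graph, and
prints the minimum-hop path from the microorganism to the phenotype.
"""

from biorel.deppath import build_undirected_graph, shortest_dependency_path
from biorel.parses import SentenceGraph, Token

words = ["Enterococcus", "is", "a", "cause", "of", "Gram-positive", "infection"]
edges = [
    (3, 0, "nsubj"), (3, 1, "cop"), (3, 2, "det"),
    (3, 4, "advmod"), (3, 6, "prep_of"), (6, 5, "amod"),
]
tokens, o = [], 0
for w in words:
    tokens.append(Token(w, "NN", o, o + len(w)))
    o += len(w) + 1
sent = SentenceGraph(tokens=tokens, edges=edges)

graph = build_undirected_graph(sent)
path = shortest_dependency_path(graph, 0, 5, sent)
print("token sequence:     ", " -> ".join(path.token_seq))
print("dependency types:   ", " -> ".join(path.deptype_seq))
print("path length m =", path.length)

# The token sequence walks from the microorganism entity head to the
# phenotype entity head through the undirected dependency graph; the
# m-1 dependency types label the edges along the way.  This pair of
# sequences is exactly what the path CNN channel consumes.
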