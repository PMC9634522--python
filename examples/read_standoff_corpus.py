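"""Read a standoff-annotated document (.txt/.a1/.a2 contents) and attach
a dependency parse, then list the entities with their resolved token spans.
"""

from biorel import read_standoff
from biorel.parses import SentenceGraph, Token, attach_parses

TEXT = "Salmonella was isolated from egg products in the region\n"
A1 = (
    "T1\tMicroorganism 0 10\tSalmonella\n"
    "T2\tHabitat 29 41\tegg products\n"
)
A2 = "R1\tLives_In Microorganism:T1 Location:T2\n"

doc = read_standoff(TEXT, A1, A2, doc_id="demo")

words = TEXT.split()
tokens, o = [], 0
for w in words:
    tokens.append(Token(w, "NN", o, o + len(w)))
    o += len(w) + 1
# a flat parse: every token attaches to the verb "isolated"
edges = [(2, i, "dep") for i in range(len(words)) if i != 2]
attach_parses(doc, [SentenceGraph(tokens=tokens, edges=edges)])

for ent in doc.entities:
    print(f"{ent.id} {ent.etype:14s} chars [{ent.char_start},{ent.char_end}) "
          f"tokens {ent.token_span[1]}..{ent.token_span[2]}  {ent.surface!r}")
for rel in doc.relations:
    print(f"{rel.id} {rel.rtype} between {rel.arg1_id} and {rel.arg2_id}")

# Each entity line shows the character span from the .a1 file and the
# sentence-local token range it was aligned to by character overlap;
# the relation line is the gold annotation parsed from the .a2 file.
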