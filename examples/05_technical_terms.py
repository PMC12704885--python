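"""Technical-term density and its relation to high-order entropy.

Injects rare technical terms into 20 synthetic documents at increasing
rates, measures the technical-term density (TT = matched token occurrences /
total tokens), and correlates TT with the order-1.5 Rényi entropy across
documents.  A positive Spearman rho shows that documents denser in rare
terminology carry higher tail-sensitive entropy.
"""

import numpy as np

from entroread import ZipfMandelbrotParams, inject_terms, sample_document, tt_density
from entroread.section_profile import tt_entropy_correlation
from entroread.synthetic import demo_lexicon

rng = np.random.default_rng(3)
lexicon = demo_lexicon(50)
docs = []
for k in range(20):
    rate = 0.01 * k
    seq = sample_document(ZipfMandelbrotParams(500), 10_000, rng, f"doc{k:02d}")
    doc = inject_terms(seq, lexicon, rate, rng)
    docs.append(doc)
    if k % 5 == 0:
        print(f"{doc.doc_id}: injected {rate:.2f}, measured TT {tt_density(doc, lexicon):.4f}")

rho, p = tt_entropy_correlation(docs, lexicon, alpha=1.5)
print(f"\nSpearman rho(TT, Rényi a=1.5) = {rho:.3f}, p = {p:.2e}")
print("positive rho: technical-term load and tail entropy rise together.")
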