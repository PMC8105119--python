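"""Independent brute-force re-implementation of the metaphor decision.

Pure-Python enumeration used only as a test oracle: it recomputes the
context mean, every candidate cosine and the final output-vector cosine
with plain arithmetic, entirely separate from the package's numpy path.
"""

import math


def naive_cosine(u, v):
    dot = sum(a * b for a, b in zip(u, v))
    nu = math.sqrt(sum(a * a for a in u))
    nv = math.sqrt(sum(b * b for b in v))
    if nu == 0 or nv == 0:
        raise ValueError("zero vector")
    return dot / (nu * nv)


def brute_force_decide(detected, sentence, store, ontology, threshold):
    """Return (label, best_fit, sim_out) or ("skipped", None, None)."""
    from msm.lexicons import candidate_set

    key = None
    for k in (detected.surface.lower(), detected.lemma.lower()):
        if k in store:
            key = k
            break
    if key is None:
        return "skipped", None, None

    ctx_rows = []
    for tok in sentence.tokens:
        if tok.index == detected.index:
            continue
        for k in (tok.surface.lower(), tok.lemma.lower()):
            if k in store:
                ctx_rows.append(list(store.input_vector(k)))
                break
    if not ctx_rows:
        return "skipped", None, None
    dim = len(ctx_rows[0])
    ctx = [sum(r[j] for r in ctx_rows) / len(ctx_rows) for j in range(dim)]

    cands = candidate_set(detected, ontology)
    best_word, best_sim = None, None
    for word in sorted(cands.candidates):
        if word not in store:
            continue
        sim = naive_cosine(list(store.input_vector(word)), ctx)
        if best_sim is None or sim > best_sim:
            best_word, best_sim = word, sim
    if best_word is None:
        return "skipped", None, None
    sim_out = naive_cosine(
        list(store.output_vector(key)), list(store.output_vector(best_word))
    )
    label = "metaphorical" if sim_out < threshold else "literal"
    return label, best_word, sim_out
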