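"""Independent brute-force decoding oracle used by the beam-search tests."""

import numpy as np

from moltrans import seq2seq


def exhaustive_best(params, cfg, latent, max_len, start, end):
    """Enumerate every decodable sequence (terminating at the end token or
    force-finished at max_len) and return (best indices, best logp)."""
    latent = np.asarray(latent).reshape(1, -1)
    hs, cs = seq2seq.decoder_initial_states(params, cfg, latent)
    best = {"logp": -np.inf, "seq": None}

    def recurse(prefix, logp, hs, cs, last_tok):
        probs, nh, nc = seq2seq.decoder_step(
            params, cfg, hs, cs, np.array([last_tok]))
        lp = np.log(probs[0])
        for tok in range(cfg.vocab_out_size):
            seq = prefix + (tok,)
            score = logp + lp[tok]
            if tok == end or len(seq) == max_len:
                if score > best["logp"]:
                    best["logp"] = score
                    best["seq"] = seq
            else:
                recurse(seq, score, nh, nc, tok)

    recurse((), 0.0, hs, cs, start)
    return best["seq"], best["logp"]
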