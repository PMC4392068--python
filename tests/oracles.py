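"""Independent brute-force oracles used to check the implementation."""

from __future__ import annotations

_DIPLOID_GAMETES = {0: {0}, 1: {0, 1}, 2: {1}}


def gamete_enumeration_oracle(c: int, m: int, f: int, x_male: bool = False, x_female: bool = False) -> str:
    """Classify inheritance by listing every consistent gamete pair.

    ``c``/``m``/``f`` are alt-allele counts for child, mother, father
    (haploid counts on X for males). Independent of the package classifier.
    """
    if c == 0:
        return "uninformative"
    if x_male:
        return "maternal" if 1 in _DIPLOID_GAMETES[m] else "de_novo"
    maternal = _DIPLOID_GAMETES[m]
    paternal = {f} if x_female else _DIPLOID_GAMETES[f]
    pairs = [(gm, gf) for gm in maternal for gf in paternal if gm + gf == c]
    if not pairs:
        return "de_novo" if (m == 0 and f == 0) else "mendelian_error"
    if c >= 2:
        return "biparental"
    origins = {"maternal" if gm else "paternal" for gm, gf in pairs}
    if len(origins) == 1:
        return origins.pop()
    return "inherited_ambiguous"
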