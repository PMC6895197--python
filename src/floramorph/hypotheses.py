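"""Built-in modularity hypotheses for the 37-landmark Merianieae flower scheme.

Landmark numbering: 1-10 stamen appendage tips, 11-20 stamen appendage bases,
21-30 anther pores, 31 style base, 32 stigma, 33-37 petal tips.  Stamen ``i``
carries appendage tip ``i``, appendage base ``10+i`` and pore ``20+i``.

Five alternative partitions of the flower are provided:

* **H1** (developmental): four organ whorls — petals, stamen whorl 1, stamen
  whorl 2, carpels.  Which stamens belong to which whorl is morphology the
  landmark scheme does not encode, so the whorl-1 stamen set is a parameter
  (default: stamens 1-5).
* **H2** (attraction/reproduction): showy sterile petals vs all fertile organs.
* **H3** (attraction/efficiency): petals + stamen appendages attract; the
  pore/stigma complex mediates pollen transfer.
* **H4** (alternative attraction/efficiency): stamen appendages attract;
  petals + pore/stigma complex mediate fit with the pollinator.
* **H5** (tribe-specific, 3 modules): petals (attraction), stamen appendages
  (pollen expulsion), pore/stigma complex (efficiency).
"""

from __future__ import annotations

from .io_formats import ModuleHypothesis

__all__ = ["builtin_hypotheses", "default_landmark_labels"]


def default_landmark_labels(p: int = 37) -> list[str]:
    return [str(k) for k in range(1, p + 1)]


def _span(*ranges) -> list[str]:
    out = []
    for a, b in ranges:
        out.extend(str(k) for k in range(a, b + 1))
    return out


def builtin_hypotheses(whorl1_stamens: tuple[int, ...] = (1, 2, 3, 4, 5)) -> list[ModuleHypothesis]:
    """The five flower modularity hypotheses on the 37-landmark scheme.

    Parameters
    ----------
    whorl1_stamens
        Stamen numbers (1-10) forming the first androecium whorl in H1; the
        remaining stamens form whorl 2.
    """
    w1 = sorted(set(int(s) for s in whorl1_stamens))
    if not w1 or not set(w1) <= set(range(1, 11)) or len(w1) == 10:
        raise ValueError("whorl1_stamens must be a proper nonempty subset of 1..10")
    w2 = [s for s in range(1, 11) if s not in w1]

    def stamen_landmarks(stamens):
        return [str(s) for s in stamens] + [str(10 + s) for s in stamens] + [str(20 + s) for s in stamens]

    petals = _span((33, 37))
    carpels = ["31", "32"]
    appendages = _span((1, 20))
    pore_stigma = _span((21, 30)) + carpels

    def hyp(name, modules: dict[str, list[str]]) -> ModuleHypothesis:
        assignment = {lm: mod for mod, lms in modules.items() for lm in lms}
        return ModuleHypothesis(name, assignment, list(modules))

    return [
        hyp("H1", {
            "petal_whorl": petals,
            "stamen_whorl_1": stamen_landmarks(w1),
            "stamen_whorl_2": stamen_landmarks(w2),
            "carpel_whorl": carpels,
        }),
        hyp("H2", {"attraction": petals, "reproduction": _span((1, 32))}),
        hyp("H3", {"attraction": appendages + petals, "efficiency": pore_stigma}),
        hyp("H4", {"attraction": appendages, "efficiency": petals + pore_stigma}),
        hyp("H5", {"corolla": petals, "appendages": appendages, "efficiency": pore_stigma}),
    ]
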