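"""The nine analysis cases: measured output x substitute-kinetics form.

Case ids follow the fixed enumeration used throughout the reports:

    (1) y=nu3, mu_hat_O    (2) y=nu1, mu_hat_O    (3) y=nu2, mu_hat_O
    (4) y=nu3, mu_hat_S    (5) y=nu1, mu_hat_S    (6) y=nu2, mu_hat_S
    (7) y=nu1, mu_hat_SO   (8) y=nu2, mu_hat_SO   (9) y=nu3, mu_hat_SO
"""

from typing import NamedTuple


class CaseSpec(NamedTuple):
    case_id: int
    output_index: int  # measured state, 1-based
    form: str          # substitute Monod form: 'S', 'O' or 'SO'


#: (output_index, form) per case, in enumeration order
_CASES = ((3, "O"), (1, "O"), (2, "O"),
          (3, "S"), (1, "S"), (2, "S"),
          (1, "SO"), (2, "SO"), (3, "SO"))

ALL_CASES = tuple(CaseSpec(i + 1, out, form)
                  for i, (out, form) in enumerate(_CASES))

#: cases whose measured output is the biomass nu1; only these have wash-out
#: sub-cases (the measured output itself can sit at zero)
WASHOUT_CASES = frozenset(c.case_id for c in ALL_CASES if c.output_index == 1)

SUBCASES = ("generic", "washout_ic", "washout_asymptotic")


def enumerate_cases():
    """All nine (output_index, substitute form) pairs in case order."""
    return [(c.output_index, c.form) for c in ALL_CASES]


def case_spec(case_id: int) -> CaseSpec:
    if case_id not in range(1, 10):
        raise ValueError(f"case id must be in 1..9, got {case_id}")
    return ALL_CASES[case_id - 1]
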