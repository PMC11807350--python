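"""Compare two classifiers with McNemar and Bhapkar paired tests.

McNemar works on paired binary correctness via the discordant counts;
Bhapkar generalizes it to multi-class outcomes (multi-label prediction
sets become composite classes).  On two categories Bhapkar reduces to
M / (1 - M/n) with M the uncorrected McNemar statistic.
"""

from salnlp import bhapkar_test, mcnemar_test
from salnlp.eval_stats import encode_labelset

# paired correctness of two systems over 60 sentences
sys_a = [True] * 40 + [False] * 20
sys_b = [True] * 30 + [False] * 10 + [True] * 12 + [False] * 8
mc = mcnemar_test(sys_a, sys_b, exact_below=0)
print(f"McNemar: chi2={mc.statistic:.3f}  p={mc.p_value:.4f}  b={mc.b} c={mc.c}")

bh = bhapkar_test(["r" if x else "w" for x in sys_a],
                  ["r" if x else "w" for x in sys_b])
closed = mc.statistic / (1 - mc.statistic / len(sys_a))
print(f"Bhapkar: chi2={bh.statistic:.3f}  df={bh.df}  p={bh.p_value:.4f}"
      f"  (closed form {closed:.3f})")

# multi-label predictions as composite classes
pred_a = [frozenset({"Population"}), frozenset({"Population", "Blinding"}), frozenset()]
pred_b = [frozenset({"Population"}), frozenset({"Blinding"}), frozenset({"Population"})]
print("composite classes:", [encode_labelset(s) for s in pred_a],
      "vs", [encode_labelset(s) for s in pred_b])
# A significant Bhapkar statistic means the two systems' outcome
# distributions differ beyond what paired sampling noise explains.
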