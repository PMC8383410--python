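"""Each dormitive form alone is a losing strategy.

Two control scenarios pit a single form of the dormitive prey against
the PA prey: the active form only (switching pinned at mu == 1) and the
sterile dormant form only (no active offspring, no termination).
"""

from dormprey import run_preset, extinction_time

active_only = run_preset("fig1a")
t_active = extinction_time(active_only, "y1")
print(f"active form alone: extinct at t = {t_active:.1f} days "
      f"(slower growth than the PA prey, no refuge)")

dormant_only = run_preset("fig1b")
t_dormant = extinction_time(dormant_only, "y2")
print(f"dormant form alone: extinct at t = {t_dormant:.1f} days "
      f"(sterile, only decays)")

# What this means: both pure strategies lose the competition — yet the
# switching strategy built from exactly these two losers wins (see
# example 01).  Two losing strategies combining into a winning one is
# the population-dynamic face of Parrondo's paradox.
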