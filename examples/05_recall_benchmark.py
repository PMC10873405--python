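"""Run a miniature recall-rate study and summarize it.

The full design sweeps p0 in {100,...,1000} and n_s in {100,...,1000} with
20 repetitions at n=1000, p=5000; here everything is shrunk so the sweep
finishes in under a minute while exercising the same machinery.
"""

from bofs import run_simulation_study, summarize

records = run_simulation_study(
    p0_grid=[10, 20],
    n_s_grid=[10, 20, 50],
    methods=[("lasso", "CV"), ("sis", "none"), ("mrmr", "none")],
    n=150, p=300, repeats=3, base_seed=0,
)
table = summarize(records)
print(table.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
# recall_mean is averaged over repetitions; n_valid counts repetitions that
# produced a ranking (failures are kept as NA rows, not dropped silently).
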