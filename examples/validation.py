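"""Ground-truth recovery validation of the measurement pipeline.

Runs the noise-free prescription grid and the seeded noise study and
prints the summary table with PASS/FAIL against the stated tolerances.
"""

from nucarray.validate import run_validation

summary = run_validation(seed=1, n_replicates=200, sigma=0.5)
print(summary.as_frame().to_string(index=False))
print()
print(f"overall: {'PASS' if summary.overall_pass else 'FAIL'}")
print()
print("The noise-free grid must recover prescribed linker angles to within")
print("0.5° (the construction is exact, so the residual is numerical); with")
print("0.5 Å coordinate noise at least 95% of measured angles must stay")
print("within 3° of the construction truth.")
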