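"""Does a white piece of chalk confirm "ravens are black"?

Increment experiment on a base sample a=d=20, b=c=10: compare the effect
of one more black raven (da=1) against one more non-black non-raven
(dd=1) for each measure.  A measure consistent with the Nicod criterion
should reward the raven and ignore the chalk.
"""

from confirmlab import ContingencyTable, nicod_fisher_check, raven_experiment

base = ContingencyTable(20, 10, 10, 20)
rows = raven_experiment(base, ["D", "M", "C", "Z", "S", "N", "F", "c*"])

print(f"base counts {base.as_tuple()}")
print(f"{'measure':>8s} {'base':>7s} {'+raven':>7s} {'+chalk':>7s} {'advantage':>10s}  Nicod-Fisher")
for name, row in rows.items():
    nf = "yes" if nicod_fisher_check(name, base) else "no"
    print(
        f"{name:>8s} {row.base_value:7.3f} {row.after_da:7.3f} "
        f"{row.after_dd:7.3f} {row.advantage:+10.3f}  {nf}"
    )

print()
print("Only c* gives the extra raven a larger boost than the extra chalk")
print("(positive advantage) and is untouched by e0-examples: the prediction")
print("confirmation reading dissolves the raven paradox.")
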