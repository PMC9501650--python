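# Pizza portion-normalization rules.
#
# Large pizza chains publish values on inconsistent bases (per slice or per
# whole pizza) across size classes.  Following the convention of the leading
# UK pizza chain, items described as large / family / for sharing / medium
# are normalized to the values for exactly 3 slices, and items described as
# small / individual to the whole pizza.
#
# "basis" declares how the source publishes the size class (per slice or per
# whole pizza); "portion" declares the normalization target.  slices_per_pizza
# converts between the two when the source basis does not match the target.
slices_per_pizza: 8
sections: [pizzas]
sizes:
  large: {basis: slice, portion: three_slices}
  family: {basis: slice, portion: three_slices}
  for sharing: {basis: slice, portion: three_slices}
  sharing: {basis: slice, portion: three_slices}
  medium: {basis: slice, portion: three_slices}
  small: {basis: whole, portion: whole}
  individual: {basis: whole, portion: whole}
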