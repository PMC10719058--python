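# Claim classification patterns, checked in order: disease risk reduction,
# nonpermitted compositional, nutrient function, nutrient content; anything
# unmatched is 'other'.  Patterns are case-insensitive substrings on
# normalised text.  Seeded from typical complementary-food label claims and
# standard Codex claim phrasing; editable.
version: 1
order:
  - disease_risk_reduction
  - nonpermitted_compositional
  - nutrient_function
  - nutrient_content
patterns:
  disease_risk_reduction:
    - reduce the risk
    - reduces the risk
    - reduces risk
    - lower the risk
    - lowers the risk
    - prevents
    - prevention of
    - protects against
  nonpermitted_compositional:
    - no added sugar
    - no added salt
    - no added
    - without added
    - free from
    - sugar free
    - salt free
    - gluten free
    - dairy free
    - naturally occurring
    - no artificial
    - no preservative
    - no preservatives
    - no colouring
    - no colourings
    - no coloring
    - no flavouring
    - no flavourings
    - unsweetened
    - organic
    - all natural
    - 100% natural
    - 100% fruit
    - natural ingredients
    - non gmo
    - gmo free
    - preservative free
  nutrient_function:
    - helps
    - help support
    - supports
    - aids
    - contributes to
    - for healthy growth
    - for growth and development
    - for brain development
    - for the immune system
    - immune support
    - builds strong
    - good for digestion
  nutrient_content:
    - high in
    - rich in
    - source of
    - good source of
    - excellent source of
    - low in
    - low fat
    - low sugar
    - low salt
    - low sodium
    - contains vitamin
    - contains iron
    - contains calcium
    - contains zinc
    - contains omega
    - contains dha
    - contains fibre
    - contains fiber
    - contains protein
    - with vitamin
    - with iron
    - with calcium
    - with dha
    - plus iron
    - fortified with
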