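# Shipped instrument specifications for the seven questionnaires.
#
# Reverse-item sets and the DEBQ item->domain mapping are editable data,
# not code: they follow the instruments' published validation papers and
# every shipped set is checked against the declared score ranges by the
# scoring engine's min/max validation.
#
# aggregation: sum | mean | yes_count (yes/no items coded 1/0)

tas20:
  description: Toronto Alexithymia Scale (alexithymia; three domains)
  item_count: 20
  scale: {low: 1, high: 5}   # 5-point items honour the declared domain ranges
  reverse_items: [4, 5, 10, 18, 19]
  aggregation: sum
  domains:
    DIF: {items: [1, 3, 6, 7, 9, 13, 14], range: [7, 35]}
    DDF: {items: [2, 4, 11, 12, 17], range: [5, 25]}
    EOT: {items: [5, 8, 10, 15, 16, 18, 19, 20], range: [8, 40]}

pbc:
  description: Private Body Consciousness (awareness of internal sensations)
  item_count: 5
  scale: {low: 1, high: 5}
  reverse_items: []
  aggregation: sum
  domains:
    PBC: {items: [1, 2, 3, 4, 5], range: [5, 25]}

sp:
  description: Sensitivity to Punishment (SPSRQ, Italian 23-item form)
  item_count: 23
  scale: {low: 0, high: 1}
  reverse_items: []
  aggregation: yes_count
  domains:
    SP: {items: [1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 11, 12, 13, 14, 15, 16, 17, 18, 19, 20, 21, 22, 23], range: [0, 23]}

sr:
  description: Sensitivity to Reward (SPSRQ, Italian 18-item form)
  item_count: 18
  scale: {low: 0, high: 1}
  reverse_items: []
  aggregation: yes_count
  domains:
    SR: {items: [1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 11, 12, 13, 14, 15, 16, 17, 18], range: [0, 18]}

fns:
  description: Food Neophobia Scale
  item_count: 10
  scale: {low: 1, high: 7}
  reverse_items: [1, 4, 6, 9, 10]
  aggregation: sum
  domains:
    FNS: {items: [1, 2, 3, 4, 5, 6, 7, 8, 9, 10], range: [10, 70]}

dssf:
  description: Disgust Scale short form (core disgust sensitivity)
  item_count: 8
  scale: {low: 1, high: 5}
  reverse_items: []
  aggregation: sum
  domains:
    DS: {items: [1, 2, 3, 4, 5, 6, 7, 8], range: [8, 40]}

debq:
  description: Dutch Eating Behavior Questionnaire (three domains, mean-scored)
  item_count: 33
  scale: {low: 1, high: 5}
  reverse_items: [21]
  aggregation: mean
  domains:
    emotional: {items: [1, 3, 5, 8, 10, 13, 16, 20, 23, 25, 28, 30, 32], range: [1, 5]}
    external: {items: [2, 6, 9, 12, 15, 18, 21, 24, 27, 33], range: [1, 5]}
    restrained: {items: [4, 7, 11, 14, 17, 19, 22, 26, 29, 31], range: [1, 5]}

htas:
  description: Health and Taste Attitudes Scale (craving for sweet foods, food as reward)
  item_count: 12
  scale: {low: 1, high: 7}
  reverse_items: [3, 6, 9]
  aggregation: mean
  domains:
    CSF: {items: [1, 2, 3, 4, 5, 6], range: [1, 7]}
    FR: {items: [7, 8, 9, 10, 11, 12], range: [1, 7]}
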