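# Header synonym map: normalized header text -> canonical field name.
#
# Headers are normalized before lookup (case-fold, trim, collapse internal
# whitespace, underscores to spaces, per-100g suffix detection, then a
# fallback lookup with the trailing unit parenthetical stripped), so entries
# here are written in normalized form.  The map is many-to-one onto the
# canonical field set and deliberately extensible: add rows as new source
# dialects appear.
item id: item_id
item: item_name
item name: item_name
name: item_name
product name: item_name
menu item: item_name
menu section: menu_section
section: menu_section
category: menu_section
description: item_description
item description: item_description

energy: energy_kcal
energy kcal: energy_kcal
energy (kcal): energy_kcal
kcal: energy_kcal
calories: energy_kcal
energy kj: energy_kj
energy (kj): energy_kj
kj: energy_kj

fat: fat
total fat: fat
fat g: fat
saturated fat: saturated_fat
sat fat: saturated_fat
saturates: saturated_fat
of which saturates: saturated_fat
saturated fat g: saturated_fat
carbohydrate: carbohydrate
carbohydrates: carbohydrate
carbs: carbohydrate
carbohydrate g: carbohydrate
sugar: sugar
sugars: sugar
sugar content: sugar
of which sugars: sugar
total sugars: sugar
sugars g: sugar
protein: protein
protein g: protein
salt: salt
salt g: salt
fibre: fiber
fiber: fiber
dietary fibre: fiber
dietary fiber: fiber
fiber g: fiber

serving weight: serving_weight
serving weight g: serving_weight
serving size: serving_weight
portion size: serving_weight
portion weight: serving_weight
weight: serving_weight
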