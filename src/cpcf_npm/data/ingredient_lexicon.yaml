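# Ingredient-class lexicon: one synonym list per class.
# Matching is case-insensitive on normalised tokens; multi-word terms match
# as contiguous word sequences; the longest match wins.  Edit freely — the
# lists are seeded with terms common on purée/meal labels, not exhaustive.
version: 1
classes:
  dairy:
    - milk
    - whole milk
    - skimmed milk
    - milk powder
    - milk solids
    - yogurt
    - yoghurt
    - fromage frais
    - custard
    - cream
    - butter
    - buttermilk
    - whey
    - casein
  cheese:
    - cheese
    - cheesy
    - cheddar
    - parmesan
    - mozzarella
    - emmental
    - gouda
    - ricotta
    - mascarpone
  fruit:
    - apple
    - banana
    - pear
    - mango
    - peach
    - apricot
    - strawberry
    - raspberry
    - blueberry
    - blackberry
    - cherry
    - plum
    - prune
    - grape
    - raisin
    - orange
    - pineapple
    - papaya
    - guava
    - melon
    - watermelon
    - kiwi
    - lychee
    - date
    - fig
    - coconut
    - avocado
    - fruit
    - fruit puree
    - fruit purée
  vegetable:
    - carrot
    - courgette
    - zucchini
    - pumpkin
    - squash
    - butternut squash
    - sweet potato
    - potato
    - tomato
    - spinach
    - broccoli
    - cauliflower
    - parsnip
    - swede
    - beetroot
    - beet
    - corn
    - sweetcorn
    - onion
    - leek
    - celery
    - cabbage
    - kale
    - cucumber
    - capsicum
    - pepper
    - mushroom
    - vegetable
    - vegetables
  legume:
    - pea
    - peas
    - green pea
    - chickpea
    - lentil
    - bean
    - beans
    - green bean
    - kidney bean
    - soybean
    - soya
    - edamame
    - pulse
  cereal:
    - rice
    - rice flour
    - brown rice
    - pasta
    - macaroni
    - noodle
    - wheat
    - wheat flour
    - flour
    - oat
    - oats
    - oatmeal
    - barley
    - maize
    - cornflour
    - corn starch
    - cornstarch
    - semolina
    - couscous
    - millet
    - rye
    - spelt
    - risotto
  pseudocereal:
    - quinoa
    - chia
    - buckwheat
    - amaranth
  meat:
    - chicken
    - beef
    - pork
    - lamb
    - turkey
    - duck
    - veal
    - ham
    - liver
    - meat
  fish:
    - fish
    - salmon
    - tuna
    - cod
    - hake
    - pollock
    - sardine
    - anchovy
    - mackerel
    - trout
    - sea bass
    - shrimp
    - prawn
  water:
    - water
    - cooking water
    - spring water
  oil_fat:
    - oil
    - rapeseed oil
    - sunflower oil
    - olive oil
    - canola oil
    - palm oil
    - coconut oil
    - vegetable oil
    - fat
  sugar_sweetener:
    - sugar
    - sucrose
    - glucose
    - fructose
    - dextrose
    - honey
    - syrup
    - molasses
    - nectar
    - sweetener
    - stevia
    - sucralose
    - aspartame
    - acesulfame
    - saccharin
  other:
    - salt
    - herbs
    - spice
    - spices
    - starch
    - lemon juice
    - lime juice
    - vitamin c
    - ascorbic acid
    - citric acid
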