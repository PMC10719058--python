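# Added sugar / sweetener lexicon.
# Four sweetener classes: all mono- and disaccharides; syrups, nectars and
# honey; fruit juices or concentrated/powdered fruit juice (lemon and lime
# juice excluded); and nonsugar sweeteners.  Term lists are editable; the
# juice class is pattern-based (any ingredient containing the word "juice"
# unless it also names lemon or lime).  Fruit purée as an ingredient is NOT
# an added sugar here — it is governed by the separate fruit-content rule.
version: 1
classes:
  mono_disaccharide:
    - sugar
    - sugars
    - brown sugar
    - cane sugar
    - sugarcane
    - palm sugar
    - coconut sugar
    - beet sugar
    - icing sugar
    - invert sugar
    - sucrose
    - glucose
    - fructose
    - dextrose
    - lactose
    - maltose
    - galactose
    - caramel
  syrup_nectar_honey:
    - syrup
    - syrups
    - honey
    - molasses
    - treacle
    - agave
    - agave syrup
    - maple syrup
    - blossom nectar
    - nectar
    - malted barley syrup
    - brown rice syrup
    - corn syrup
    - glucose syrup
    - rice syrup
    - golden syrup
    - high fructose corn syrup
  nonsugar_sweetener:
    - saccharin
    - acesulfame
    - acesulfame k
    - aspartame
    - sucralose
    - stevia
    - steviol glycosides
    - cyclamate
    - neotame
    - advantame
    - xylitol
    - sorbitol
    - maltitol
    - erythritol
    - sweetener
juice_words: [juice, juices]
juice_exclusions: [lemon, lime]
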