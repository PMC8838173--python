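# Synthetic per-100 g composition fixture: invented but physiologically plausible values.
# Not a national food-composition database; used only to drive the synthetic study generator.
label,food_type,kind,energy_kcal,fat_g,carb_g,protein_g,fiber_g,alcohol_g,typical_weight_g
black tea,tea_coffee,beverage,1,0,0.2,0,0,0,200
coffee,tea_coffee,beverage,2,0,0.3,0.1,0,0,150
cola,soft_drinks,beverage,42,0,10.5,0,0,0,250
lemonade,soft_drinks,beverage,40,0,10,0,0,0,250
orange juice,fruit_juice,beverage,45,0.2,10.4,0.7,0.2,0,200
apple juice,fruit_juice,beverage,46,0.1,11.3,0.1,0.1,0,200
soy drink,plant_milk,beverage,42,1.8,3.3,3.3,0.5,0,200
lettuce,leafy_vegetables,food,15,0.2,2.9,1.4,1.3,0,80
spinach,leafy_vegetables,food,23,0.4,3.6,2.9,2.2,0,150
carrots,root_vegetables,food,41,0.2,9.6,0.9,2.8,0,120
beetroot,root_vegetables,food,43,0.2,9.6,1.6,2.8,0,100
tomatoes,fruiting_vegetables,food,18,0.2,3.9,0.9,1.2,0,120
zucchini,fruiting_vegetables,food,17,0.3,3.1,1.2,1.0,0,150
apple,pome_stone_fruit,food,52,0.2,13.8,0.3,2.4,0,140
peach,pome_stone_fruit,food,39,0.3,9.5,0.9,1.5,0,130
strawberries,berries,food,32,0.3,7.7,0.7,2.0,0,120
wholegrain bread,bread,food,247,3.4,41.3,13.0,7.0,0,60
white bread,bread,food,265,3.2,49.0,9.0,2.7,0,50
pasta cooked,pasta,food,158,0.9,30.9,5.8,1.8,0,180
muesli,breakfast_cereals,food,362,5.9,66.2,10.6,7.6,0,50
rice cooked,rice,food,130,0.3,28.2,2.7,0.4,0,160
potatoes boiled,tubers,food,87,0.1,20.1,1.9,1.8,0,180
potato gratin,tubers,food,132,7.5,12.5,3.6,1.1,0,220
lentils cooked,legumes,food,116,0.4,20.1,9.0,7.9,0,150
beef steak,red_meat,food,217,11.8,0,26.1,0,0,150
pork chop,red_meat,food,231,14.0,0,25.7,0,0,140
chicken breast,poultry,food,165,3.6,0,31.0,0,0,130
salmon fillet,fish,food,208,13.4,0,20.4,0,0,130
cod fillet,fish,food,82,0.7,0,17.8,0,0,130
shrimp,seafood,food,99,0.3,0.2,24.0,0,0,90
salami,processed_meat,food,336,26.0,1.2,22.0,0,0,40
boiled egg,eggs,food,155,10.6,1.1,12.6,0,0,60
tofu,meat_substitutes,food,76,4.8,1.9,8.1,0.3,0,120
gruyere cheese,cheese,food,413,32.3,0.4,29.8,0,0,40
plain yogurt,yogurt,food,61,3.3,4.7,3.5,0,0,150
whole milk,milk,beverage,64,3.6,4.8,3.3,0,0,200
olive oil,vegetable_oils,food,884,100,0,0,0,0,10
butter,butter,food,717,81.1,0.1,0.9,0,0,10
almonds,nuts_seeds,food,579,49.9,21.6,21.2,12.5,0,30
potato chips,salty_snacks,food,536,34.6,52.9,7.0,4.4,0,40
croissant,pastries,food,406,21.0,45.8,8.2,2.6,0,70
dark chocolate,chocolate_confectionery,food,546,31.3,61.2,4.9,7.0,0,25
white sugar,sugar_honey,food,387,0,99.8,0,0,0,8
honey,sugar_honey,food,304,0,82.4,0.3,0.2,0,15
lager beer,beer,beverage,43,0,3.6,0.5,0,3.6,330
red wine,wine,beverage,85,0,2.6,0.1,0,10.6,120
mojito cocktail,spirits_cocktails,beverage,97,0,10.9,0,0,8.0,200
tomato sauce,sauces,food,59,2.4,8.1,1.6,1.8,0,80
salad dressing,sauces,food,449,44.5,8.9,1.1,0.2,0,30
vegetable soup,soups,food,36,1.3,4.8,1.4,1.2,0,250
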