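type,group,category
tea_coffee,NaNs beverages,beverages
soft_drinks,NaS beverages,beverages
fruit_juice,Juice,beverages
plant_milk,Milk substitutes,beverages
leafy_vegetables,Vegetables,vegetables & fruit
root_vegetables,Vegetables,vegetables & fruit
fruiting_vegetables,Vegetables,vegetables & fruit
pome_stone_fruit,Fruit,vegetables & fruit
berries,Fruit,vegetables & fruit
bread,Cereals & cereal-based products,grains & potatoes
pasta,Cereals & cereal-based products,grains & potatoes
breakfast_cereals,Cereals & cereal-based products,grains & potatoes
rice,"Rice, rice-based products",grains & potatoes
tubers,"Potatoes, legumes & beans",grains & potatoes
legumes,"Potatoes, legumes & beans",grains & potatoes
red_meat,Meat & poultry,protein foods
poultry,Meat & poultry,protein foods
fish,Fish & seafood,protein foods
seafood,Fish & seafood,protein foods
processed_meat,Unclassified meat,protein foods
eggs,Eggs & meat substitutes,protein foods
meat_substitutes,Eggs & meat substitutes,protein foods
cheese,Dairy products (excl. milk),protein foods
yogurt,Dairy products (excl. milk),protein foods
milk,Milk & milk-based beverages,protein foods
vegetable_oils,Fats & oils,"oils, fats & nuts"
butter,Fats & oils,"oils, fats & nuts"
nuts_seeds,Seeds & nuts,"oils, fats & nuts"
salty_snacks,Salty snacks,"sweets, snacks & alcohol"
pastries,Sweet dishes,"sweets, snacks & alcohol"
chocolate_confectionery,Sweet dishes,"sweets, snacks & alcohol"
sugar_honey,Sweeteners,"sweets, snacks & alcohol"
beer,Alcoholic beverages,"sweets, snacks & alcohol"
wine,Alcoholic beverages,"sweets, snacks & alcohol"
spirits_cocktails,Alcoholic beverages,"sweets, snacks & alcohol"
sauces,Condiments & sauces,prepared dishes & soups
soups,Soups,prepared dishes & soups
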