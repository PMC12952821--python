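token,category
sweet,sweet
honey,sweet
caramel,caramel
caramel-like,caramel
caramelized,caramel
fruity,fruity
wine-like,fruity
apple,fruity
citrus,citrus
lemon,citrus
orange,citrus
green,green_grassy
grassy,green_grassy
cucumber,green_grassy
cucumber peel,green_grassy
floral,floral
rose,floral
violet,floral
saffron,floral
woody,woody
pine,woody
fresh pine,woody
resinous,woody
toasted,roasted_nutty
toasty,roasted_nutty
roasted,roasted_nutty
nutty,roasted_nutty
bready,roasted_nutty
almond,roasted_nutty
almond-like,roasted_nutty
smoky,smoky
sour,sour
sourness,sour
tang,sour
acidic,sour
fatty,fatty_waxy
waxy,fatty_waxy
creamy,fatty_waxy
buttery,fatty_waxy
oily,fatty_waxy
amine,amine
amine-like,amine
aminic,amine
earthy,earthy_tobacco
tobacco,earthy_tobacco
herbal,herbal
medicinal,herbal
tea,herbal
black tea,herbal
spicy,herbal
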